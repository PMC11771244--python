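"""Expression denoising decoder.

A separate model trained after the encoder, with the encoder frozen: a
single GAT layer over the learned latent representations followed by a
fully connected layer back to gene space, fitted by MSE against the
(preprocessed) expression.  Because the decoder aggregates each spot's
latent neighbourhood with attention before reconstructing, its output is a
spatially smoothed — denoised — expression profile.

Architecturally the decoder reuses the encoder stack with dims
latent -> hidden -> genes; the "latent" output of that stack is the
reconstruction.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Adam, Tensor
from .encoder import encode_tensors, init_params
from .graph import SpatialGraph

__all__ = ["train_denoiser"]


def train_denoiser(h_f: np.ndarray, sag: SpatialGraph, h_original: np.ndarray,
                   epochs: int = 300, lr: float = 1e-2, seed: int = 0,
                   hidden_dim: int = 64, return_history: bool = False):
    """Fit the GAT + FC decoder and return the denoised expression matrix.

    h_f: trained latent representations (spots x latent); h_original: the
    expression the decoder reconstructs (spots x genes).  Deterministic
    under `seed`.
    """
    h_f = np.asarray(h_f, dtype=float)
    h = np.asarray(h_original, dtype=float)
    if h_f.shape[0] != h.shape[0] or h_f.shape[0] != sag.n_spots:
        raise ValueError("latent, expression and graph spot counts differ")

    dec = init_params(gene_dim=h_f.shape[1], gat_dim=hidden_dim,
                      latent_dim=h.shape[1], seed=seed)
    opt = Adam(dec.tensors()[:3], lr=lr)  # w_gene head unused by the decoder
    x_t = Tensor(h_f)
    target = Tensor(h)
    history = []
    recon_data = None
    for _ in range(epochs):
        _, recon = encode_tensors(x_t, sag, dec)
        diff = recon - target
        loss = (diff * diff).mean()
        history.append(float(loss.data))
        recon_data = recon.data
        opt.zero_grad()
        loss.backward()
        opt.step()
    _, recon = encode_tensors(x_t, sag, dec)
    recon_data = recon.data
    if return_history:
        return recon_data, np.asarray(history)
    return recon_data
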