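"""HDF5 serialization of fitted decoders.

Every fitted decoder collapses to its evaluation form
(:class:`~megdecode.base.AffineDecoder`): optional whitening, optional
channel projection, and one affine score map.  That form is what is
stored; loading returns an :class:`AffineDecoder` with identical
predictions.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .base import AffineDecoder


def save_model(model, path, meta: dict | None = None) -> None:
    """Write a fitted decoder (anything with ``collapse()``, or an
    :class:`AffineDecoder`) to an HDF5 file."""
    aff = model if isinstance(model, AffineDecoder) else model.collapse()
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=aff.weights)
        f.create_dataset("bias", data=aff.bias)
        f.create_dataset("classes", data=aff.classes_)
        if aff.whiten_matrix is not None:
            f.create_dataset("whiten_mean", data=aff.whiten_mean)
            f.create_dataset("whiten_matrix", data=aff.whiten_matrix)
        if aff.projection is not None:
            f.create_dataset("projection", data=aff.projection)
        f.attrs["meta"] = json.dumps(meta or {})


def load_model(path) -> AffineDecoder:
    with h5py.File(path, "r") as f:
        def opt(name):
            return f[name][()] if name in f else None
        return AffineDecoder(
            weights=f["weights"][()], bias=f["bias"][()],
            classes=f["classes"][()], whiten_mean=opt("whiten_mean"),
            whiten_matrix=opt("whiten_matrix"), projection=opt("projection"))
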