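"""Subject and group functional-connectivity graphs from parcel time series."""

from __future__ import annotations

import numpy as np

from .core import AdjacencyMatrix, symmetrize_zero_diag
from .exceptions import DegenerateParcelError

#: correlations are clipped to +/-(1 - CLIP) before artanh so that
#: duplicate-region edges stay finite and cannot poison group means
CLIP = 1e-7


def subject_fc(ts: np.ndarray, modality: str = "fc") -> AdjacencyMatrix:
    """Fisher-z connectivity of one subject's parcels x timepoints series.

    Edges are ``artanh(clip(r, +/-(1-1e-7)))`` of the Pearson correlation
    between parcel time series; diagonal zero.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be parcels x timepoints")
    const = np.flatnonzero(ts.std(axis=1) == 0.0)
    if len(const):
        raise DegenerateParcelError(
            f"constant time series at parcels: {const.tolist()}", parcels=const)
    r = np.corrcoef(ts)
    z = np.arctanh(np.clip(r, -(1.0 - CLIP), 1.0 - CLIP))
    return AdjacencyMatrix(symmetrize_zero_diag(z), modality=modality,
                           confound_model="", scale="z")


def group_fc(graphs) -> AdjacencyMatrix:
    """Average z-scale subject graphs and map back to correlation scale.

    The edgewise mean of Fisher-z values is passed through tanh, restoring
    the (-1, 1) range for gradient decomposition.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("need at least one subject graph")
    P = graphs[0].n_parcels
    for g in graphs:
        if g.n_parcels != P:
            raise ValueError("all graphs must share the parcel set")
        if g.scale != "z":
            raise ValueError("group_fc expects z-scale subject graphs")
    mean_z = np.mean([g.values for g in graphs], axis=0)
    r = np.tanh(mean_z)
    return AdjacencyMatrix(symmetrize_zero_diag(r), modality=graphs[0].modality,
                           confound_model="", scale="r")
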