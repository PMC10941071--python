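"""Core parcel-level containers and their delimited-text serialization.

The package operates entirely at parcel resolution: a cortical atlas of P
parcels (two hemispheres, seven canonical resting-state networks), per-subject
parcel feature matrices (receptor binding potential, cortical thickness), and
parcel x parcel adjacency matrices derived from them.  Everything round-trips
through TSV with header rows so outputs are diffable and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidDataError

#: The seven canonical resting-state networks, ordered roughly from
#: unimodal/sensory to transmodal/associative cortex.
NETWORKS = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default")

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class ParcelAtlas:
    """Parcel geometry and labels: the coordinate frame for spins and distances.

    Attributes
    ----------
    parcel_id : (P,) int array, 0..P-1
    hemisphere : (P,) array of 'L' / 'R'; equal counts per hemisphere
    network : (P,) array of labels drawn from :data:`NETWORKS`
    sphere_xyz : (P, 3) unit vectors on the registration sphere
    centroid_xyz : (P, 3) volumetric centroids in mm
    """

    parcel_id: np.ndarray
    hemisphere: np.ndarray
    network: np.ndarray
    sphere_xyz: np.ndarray
    centroid_xyz: np.ndarray

    def __post_init__(self):
        P = len(self.parcel_id)
        if not np.array_equal(self.parcel_id, np.arange(P)):
            raise ValueError("parcel_id must be 0..P-1 in order")
        norms = np.linalg.norm(self.sphere_xyz, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidDataError("sphere coordinates must be unit-norm")
        nl = int(np.sum(self.hemisphere == "L"))
        if nl * 2 != P:
            raise InvalidDataError("hemispheres must have equal parcel counts")
        unknown = set(np.unique(self.network)) - set(NETWORKS)
        if unknown:
            raise InvalidDataError(f"unknown network labels: {sorted(unknown)}")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_id)

    def hemi_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def network_indices(self, network: str) -> np.ndarray:
        return np.flatnonzero(self.network == network)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_id,
                "hemisphere": self.hemisphere,
                "network": self.network,
                "sx": self.sphere_xyz[:, 0],
                "sy": self.sphere_xyz[:, 1],
                "sz": self.sphere_xyz[:, 2],
                "cx": self.centroid_xyz[:, 0],
                "cy": self.centroid_xyz[:, 1],
                "cz": self.centroid_xyz[:, 2],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_tsv(cls, path) -> "ParcelAtlas":
        df = pd.read_csv(path, sep="\t")
        return cls(
            parcel_id=df["parcel_id"].to_numpy(),
            hemisphere=df["hemisphere"].to_numpy(dtype=object),
            network=df["network"].to_numpy(dtype=object),
            sphere_xyz=df[["sx", "sy", "sz"]].to_numpy(dtype=float),
            centroid_xyz=df[["cx", "cy", "cz"]].to_numpy(dtype=float),
        )


@dataclass
class ParcelFeatureMatrix:
    """Subjects x parcels values of one modality, with subject covariates.

    ``values[s, p]`` is subject ``s``'s value at parcel ``p`` (binding
    potential is unitless, thickness is in mm).  ``covariates`` is indexed by
    subject id and carries ``age`` (years), ``sex`` (0/1) and optionally
    ``fd`` (mean framewise displacement, mm).
    """

    values: np.ndarray
    subjects: list
    covariates: pd.DataFrame
    modality: str = "bp"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a subjects x parcels matrix")
        if len(self.subjects) != self.values.shape[0]:
            raise ValueError("subject list does not match values rows")
        if list(self.covariates.index) != list(self.subjects):
            raise ValueError("covariates must be indexed by the same subjects")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "ParcelFeatureMatrix":
        return ParcelFeatureMatrix(
            values=np.array(values, dtype=float),
            subjects=list(self.subjects),
            covariates=self.covariates.copy(),
            modality=self.modality,
        )

    def to_tsv(self, path) -> None:
        # parcels x subjects on disk, subject ids as the header row
        df = pd.DataFrame(self.values.T, columns=self.subjects)
        df.insert(0, "parcel_id", np.arange(self.n_parcels))
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_tsv(cls, path, covariates: pd.DataFrame, modality: str = "bp"):
        df = pd.read_csv(path, sep="\t")
        subjects = [c for c in df.columns if c != "parcel_id"]
        values = df[subjects].to_numpy(dtype=float).T
        return cls(values=values, subjects=subjects,
                   covariates=covariates.loc[subjects], modality=modality)


@dataclass
class AdjacencyMatrix:
    """Symmetric parcels x parcels graph with self-edges excluded.

    ``scale`` records whether edges are correlation-scale ('r') or Fisher
    z-scale ('z'); ``confound_model`` describes the residualization applied
    upstream (e.g. ``"age+age2+sex"`` or ``"zscore"``).
    """

    values: np.ndarray
    modality: str = ""
    confound_model: str = ""
    scale: str = "r"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.all(np.isfinite(v)):
            raise InvalidDataError("adjacency contains non-finite entries")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise InvalidDataError("adjacency must be symmetric to 1e-12")
        if np.any(np.diag(v) != 0.0):
            raise InvalidDataError("diagonal must be exactly zero (self-edges excluded)")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    def upper_edges(self) -> np.ndarray:
        iu = np.triu_indices(self.n_parcels, k=1)
        return self.values[iu]

    def to_tsv(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        df = pd.DataFrame(self.values)
        df.to_csv(path, sep="\t", index=False, header=False, float_format="%.12g")
        if sidecar:
            meta = {
                "modality": self.modality,
                "confound_model": self.confound_model,
                "scale": self.scale,
                "n_parcels": int(self.n_parcels),
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2, sort_keys=True) + "\n"
            )

    @classmethod
    def from_tsv(cls, path) -> "AdjacencyMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            values=values,
            modality=meta.get("modality", ""),
            confound_model=meta.get("confound_model", ""),
            scale=meta.get("scale", "r"),
        )


def symmetrize_zero_diag(m: np.ndarray) -> np.ndarray:
    """Return 0.5*(M + M^T) with an exactly zero diagonal."""
    out = 0.5 * (m + m.T)
    np.fill_diagonal(out, 0.0)
    return out
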