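"""Per-residue RMSF from coordinate ensembles and binary flexibility labels.

The per-protein flexibility target is built in three steps: optimal rigid
superposition of every frame onto an iteratively refined mean structure,
per-residue root-mean-square fluctuation about the mean, and aggregation —
replicate-averaged per-residue profile, then residue average — to one scalar
per protein.  Proteins whose scalar exceeds the dataset-wide mean are
labeled flexible; a value exactly at the threshold counts as non-flexible
(the threshold rule is strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ShapeError

FLEXIBLE = "flexible"
NON_FLEXIBLE = "non_flexible"


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Angstrom) of one replicate."""

    per_residue: np.ndarray
    replicate_id: str = ""

    def __post_init__(self):
        self.per_residue = np.asarray(self.per_residue, dtype=float)
        if np.any(self.per_residue < 0):
            raise ShapeError("RMSF values must be non-negative")

    def __len__(self) -> int:
        return len(self.per_residue)


@dataclass
class FlexibilityRecord:
    """One protein's aggregate RMSF and its flexibility label."""

    protein_id: str
    rmsf_scalar: float
    label: str

    def __post_init__(self):
        if self.rmsf_scalar < 0:
            raise ShapeError("rmsf_scalar must be >= 0")
        if self.label not in (FLEXIBLE, NON_FLEXIBLE):
            raise ShapeError(f"unknown label {self.label!r}")


def kabsch_superpose(mobile, reference):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(aligned, rmsd)`` where the rotation is proper (det +1).
    Collinear point sets trigger a conditioning warning but still return the
    best-effort alignment.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ShapeError(
            f"point sets must both be (n, 3); got {mobile.shape} vs {reference.shape}"
        )
    if mobile.shape[0] < 3:
        raise ShapeError("need >= 3 points for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        warnings.warn(
            "near-collinear point set: superposition is ill-conditioned",
            stacklevel=2,
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    aligned = P @ R.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=1))))
    return aligned, rmsd


def rmsf_profile(replicate, replicate_id: str = "", max_iter: int = 10) -> RMSFProfile:
    """RMSF of each residue about the iteratively refined mean structure.

    All frames are aligned to the running mean, the mean is recomputed, and
    iteration stops when the mean shifts by less than 1e-6 A (or after
    ``max_iter`` rounds).
    """
    frames = np.asarray(replicate, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ShapeError(f"replicate must be (n_frames, n_residues, 3), got {frames.shape}")
    if frames.shape[0] < 2:
        raise ShapeError("need >= 2 frames for RMSF")
    mean = frames[0].copy()
    aligned = frames.copy()
    for _ in range(max_iter):
        for f in range(frames.shape[0]):
            aligned[f], _ = kabsch_superpose(frames[f], mean)
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < 1e-6:
            break
    disp_sq = np.sum((aligned - mean[None]) ** 2, axis=2)
    return RMSFProfile(np.sqrt(disp_sq.mean(axis=0)), replicate_id=replicate_id)


def aggregate_rmsf(profiles) -> float:
    """Replicate-average the per-residue profile, then average over residues."""
    if not profiles:
        raise DegenerateInputError("no RMSF profiles supplied")
    arrays = [np.asarray(p.per_residue if isinstance(p, RMSFProfile) else p, dtype=float)
              for p in profiles]
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise ShapeError(f"profiles have inconsistent lengths: {sorted(lengths)}")
    per_residue = np.mean(arrays, axis=0)
    return float(per_residue.mean())


def flexibility_labels(values: dict, threshold="dataset_mean"):
    """Label each protein flexible iff its RMSF scalar strictly exceeds the threshold.

    ``threshold`` is either the string ``"dataset_mean"`` or an explicit
    number.  A value exactly equal to the threshold is non-flexible.
    """
    if not values:
        raise DegenerateInputError("empty RMSF value map")
    if threshold == "dataset_mean":
        if len(values) < 2:
            raise DegenerateInputError(
                "dataset_mean threshold needs >= 2 proteins"
            )
        thr = float(np.mean(list(values.values())))
    else:
        thr = float(threshold)
    return [
        FlexibilityRecord(
            protein_id=str(pid),
            rmsf_scalar=float(v),
            label=FLEXIBLE if v > thr else NON_FLEXIBLE,
        )
        for pid, v in values.items()
    ]
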