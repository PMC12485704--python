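"""Synthetic inputs: parametric backbones, noisy trajectories, labeled descriptor sets.

Everything the pipeline consumes can be generated here with a seed, so the
full workflow — trace -> Gauss integrals -> flexibility labels -> training —
is exercisable without downloading any database.  The generators aim for
controlled geometry and known ground truth, not physical realism: helices
are ideal cylindrical curves, coils are fixed-step self-avoiding walks, and
trajectory noise is isotropic Gaussian with a known per-residue profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from .errors import GenerationError, ParameterError
from .structure_io import CaTrace

BACKBONE_KINDS = ("helix", "strand", "hairpin", "coil", "planar_zigzag")


@dataclass
class BackboneParams:
    """Parameters of one synthetic C-alpha backbone.

    The ideal helix uses a rise of 1.5 A and a turn of 100 deg per residue
    (canonical alpha-helix geometry); its radius is derived from the bond
    length so that consecutive C-alpha distances equal ``bond_length``
    exactly (about 2.28 A, the textbook ~2.3 A), unless ``helix_radius``
    is pinned explicitly.
    """

    kind: str = "helix"
    n_residues: int = 50
    handedness: str = "right"
    bond_length: float = 3.8
    helix_rise: float = 1.5
    helix_turn_deg: float = 100.0
    helix_radius: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in BACKBONE_KINDS:
            raise ParameterError(f"unknown backbone kind {self.kind!r}")
        if self.n_residues < 7:
            raise ParameterError("n_residues must be >= 7")
        if self.bond_length <= 0:
            raise ParameterError("bond_length must be positive")
        if self.handedness not in ("right", "left"):
            raise ParameterError("handedness must be 'right' or 'left'")


def _helix(params: BackboneParams) -> np.ndarray:
    theta = np.deg2rad(params.helix_turn_deg)
    rise = params.helix_rise
    if params.helix_radius is not None:
        radius = params.helix_radius
    else:
        chord_sq = params.bond_length**2 - rise**2
        if chord_sq <= 0:
            raise ParameterError("helix rise exceeds bond length")
        radius = np.sqrt(chord_sq) / (2.0 * np.sin(theta / 2.0))
    i = np.arange(params.n_residues)
    sign = 1.0 if params.handedness == "right" else -1.0
    return np.column_stack(
        [radius * np.cos(i * theta), sign * radius * np.sin(i * theta), i * rise]
    )


def _strand(params: BackboneParams) -> np.ndarray:
    # near-linear pleated strand with a gentle twist so the curve is not planar:
    # offsets of constant magnitude rotate by ~170 deg per residue, keeping
    # consecutive distances exactly at bond_length.
    amp = 0.5
    phi = np.deg2rad(170.0)
    chord = 2.0 * amp * np.sin(phi / 2.0)
    dx = np.sqrt(params.bond_length**2 - chord**2)
    i = np.arange(params.n_residues)
    sign = 1.0 if params.handedness == "right" else -1.0
    return np.column_stack(
        [i * dx, amp * np.cos(i * phi), sign * amp * np.sin(i * phi)]
    )


def _planar_zigzag(params: BackboneParams) -> np.ndarray:
    amp = 1.0
    dx = np.sqrt(params.bond_length**2 - (2.0 * amp) ** 2)
    i = np.arange(params.n_residues)
    return np.column_stack([i * dx, amp * (-1.0) ** i, np.zeros_like(i, dtype=float)])


def _hairpin(params: BackboneParams) -> np.ndarray:
    """Two antiparallel strands joined by a semicircular turn."""
    n = params.n_residues
    b = params.bond_length
    n_turn = 3
    n_strand = (n - n_turn) // 2
    n_back = n - n_turn - n_strand
    sep = 4.8  # inter-strand separation, typical for beta hairpins
    amp = 0.5
    dx = np.sqrt(b**2 - (2 * amp) ** 2)
    pts = []
    for i in range(n_strand):
        pts.append([i * dx, amp * (-1.0) ** i, 0.0])
    # semicircular turn of n_turn points from strand end to the return strand
    start = np.array(pts[-1])
    center = start + np.array([b * 0.5, sep / 2.0, 0.0])
    angles = np.linspace(-np.pi / 2.0, np.pi / 2.0, n_turn + 2)[1:-1]
    r_turn = np.sqrt((sep / 2.0) ** 2 + (b * 0.5) ** 2)
    for a in angles:
        pts.append(
            [center[0] + r_turn * np.cos(a), center[1] + r_turn * np.sin(a), 0.3]
        )
    x0 = pts[n_strand - 1][0]
    for i in range(n_back):
        pts.append([x0 - i * dx, sep + amp * (-1.0) ** i, 0.0])
    return np.asarray(pts)


def _coil(params: BackboneParams) -> np.ndarray:
    """Fixed-step self-avoiding random walk (step 3.8 A, clearance 3.0 A)."""
    rng = np.random.default_rng(params.seed)
    step = params.bond_length
    min_dist = 3.0
    max_retries = 10_000
    retries = 0
    while True:
        pts = [np.zeros(3)]
        direction = np.array([1.0, 0.0, 0.0])
        ok = True
        while len(pts) < params.n_residues:
            placed = False
            for _ in range(50):
                retries += 1
                if retries > max_retries:
                    raise GenerationError(
                        "self-avoiding walk failed after 10^4 retries"
                    )
                # bias toward the previous direction to mimic chain stiffness
                proposal = direction + 0.9 * rng.normal(size=3)
                proposal /= np.linalg.norm(proposal)
                cand = pts[-1] + step * proposal
                if len(pts) >= 2:
                    d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
                    if d.min() < min_dist:
                        continue
                pts.append(cand)
                direction = proposal
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts)
        # dead end: restart the walk (retry budget keeps accumulating)


def make_backbone(params: BackboneParams) -> CaTrace:
    """Generate a synthetic C-alpha trace of the requested kind."""
    builder = {
        "helix": _helix,
        "strand": _strand,
        "hairpin": _hairpin,
        "coil": _coil,
        "planar_zigzag": _planar_zigzag,
    }[params.kind]
    coords = builder(params)
    return CaTrace(
        chain_id="A",
        residue_ids=np.arange(1, params.n_residues + 1),
        coords=coords,
    )


@dataclass
class TrajectoryEnsemble:
    """Replicated frame sets of C-alpha coordinates aligned to one topology."""

    replicates: list  # list of ndarray (n_frames, n_residues, 3)

    def __post_init__(self):
        if len(self.replicates) < 1:
            raise ParameterError("need >= 1 replicate")
        shapes = {r.shape[1:] for r in self.replicates}
        if len(shapes) != 1:
            raise ParameterError(f"inconsistent residue counts: {shapes}")
        if any(r.shape[0] < 2 for r in self.replicates):
            raise ParameterError("each replicate needs >= 2 frames")

    @property
    def n_residues(self) -> int:
        return self.replicates[0].shape[1]


def make_trajectory(
    reference: CaTrace,
    sigma_profile,
    n_frames: int,
    n_replicates: int,
    seed: int,
) -> TrajectoryEnsemble:
    """Frames = reference + per-residue isotropic Gaussian noise + rigid motion.

    ``sigma_profile`` gives the per-coordinate noise standard deviation for
    each residue, so the expected superposed RMSF of residue ``i`` approaches
    ``sigma_profile[i] * sqrt(3)``.  A random rotation and translation per
    frame forces downstream superposition to do real work.
    """
    sigma = np.asarray(sigma_profile, dtype=float)
    if sigma.shape != (reference.n_residues,):
        raise ParameterError(
            f"sigma_profile length {sigma.shape} != n_residues {reference.n_residues}"
        )
    if np.any(sigma < 0):
        raise ParameterError("sigma_profile must be non-negative")
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(n_replicates):
        frames = np.empty((n_frames, reference.n_residues, 3))
        for f in range(n_frames):
            noisy = reference.coords + rng.normal(size=(reference.n_residues, 3)) * sigma[:, None]
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(scale=5.0, size=3)
            frames[f] = noisy @ rot.T + shift
        replicates.append(frames)
    return TrajectoryEnsemble(replicates=replicates)


@dataclass
class SyntheticLabeledSet:
    """Labeled 30-component descriptor dataset with planted signal."""

    X: np.ndarray
    y: np.ndarray
    informative_components: tuple
    effect_size: float
    noise_sd: float
    task: str
    seed: int
    bayes_auc: float | None = None
    bayes_r2: float | None = None


def bayes_auc(effect_size: float, n_informative: int, noise_sd: float) -> float:
    """Closed-form best achievable AUC of the planted-signal classification set.

    The latent score ``s = effect * sum_j X_j`` is N(0, a^2) with
    ``a^2 = effect^2 * k``; the label is ``1{s + eps > 0}`` with
    ``eps ~ N(0, sd^2)``.  The optimal ranking is by ``s`` and the AUC is
    ``1/2 + (2/pi) * arcsin(a / sqrt(2 (a^2 + sd^2)))``.
    """
    a2 = effect_size**2 * n_informative
    if a2 == 0:
        return 0.5
    rho = np.sqrt(a2 / (2.0 * (a2 + noise_sd**2)))
    return float(0.5 + 2.0 * np.arcsin(rho) / np.pi)


def bayes_r2(effect_size: float, n_informative: int, noise_sd: float) -> float:
    """Closed-form best achievable R^2 of the planted-signal regression set."""
    a2 = effect_size**2 * n_informative
    if a2 == 0 and noise_sd == 0:
        raise ParameterError("degenerate regression target")
    return float(a2 / (a2 + noise_sd**2))


def effect_size_for_bayes_auc(
    target_auc: float, n_informative: int, noise_sd: float = 1.0
) -> float:
    """Invert :func:`bayes_auc` for the per-component effect size."""
    if not 0.5 < target_auc < 1.0:
        raise ParameterError("target AUC must be in (0.5, 1)")
    rho = np.sin((target_auc - 0.5) * np.pi / 2.0)
    a2 = 2.0 * rho**2 * noise_sd**2 / (1.0 - 2.0 * rho**2)
    return float(np.sqrt(a2 / n_informative))


def effect_size_for_bayes_r2(
    target_r2: float, n_informative: int, noise_sd: float = 1.0
) -> float:
    """Invert :func:`bayes_r2` for the per-component effect size."""
    if not 0.0 < target_r2 < 1.0:
        raise ParameterError("target R^2 must be in (0, 1)")
    a2 = noise_sd**2 * target_r2 / (1.0 - target_r2)
    return float(np.sqrt(a2 / n_informative))


def make_labeled_set(
    n: int,
    informative_components,
    effect_size: float,
    noise_sd: float,
    task: str = "classification",
    seed: int = 0,
    n_features: int = 30,
) -> SyntheticLabeledSet:
    """Standard-normal features with a planted linear signal on a few components.

    Classification: ``y = 1`` iff ``effect * sum_{j in informative} X_j + eps > 0``.
    Regression: ``y`` equals that sum.  The achievable (Bayes) AUC or R^2 is
    computed in closed form and attached to the returned set.
    """
    comps = tuple(sorted(int(c) for c in informative_components))
    if any(not 1 <= c <= n_features for c in comps):
        raise ParameterError(f"informative components must lie in 1..{n_features}")
    if effect_size > 0 and not comps:
        raise ParameterError("nonzero effect size requires informative components")
    if task not in ("classification", "regression"):
        raise ParameterError(f"unknown task {task!r}")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    idx = np.asarray(comps, dtype=int) - 1
    signal = effect_size * X[:, idx].sum(axis=1) if comps else np.zeros(n)
    noise = rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else 0.0
    latent = signal + noise
    if task == "classification":
        y = (latent > 0).astype(float)
    else:
        y = latent
    return SyntheticLabeledSet(
        X=X,
        y=y,
        informative_components=comps,
        effect_size=effect_size,
        noise_sd=noise_sd,
        task=task,
        seed=seed,
        bayes_auc=bayes_auc(effect_size, len(comps), noise_sd)
        if task == "classification"
        else None,
        bayes_r2=bayes_r2(effect_size, len(comps), noise_sd)
        if task == "regression"
        else None,
    )
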