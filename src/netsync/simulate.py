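"""Synthetic resting-state study generator with known ground truth.

Builds group studies with planted network spatial maps, group-specific
inter-network correlation matrices, low-frequency latent signals,
motion-like and tissue confounds, Gaussian noise, and behavior scores
tied to a chosen network pair — together with a truth record that fully
determines regeneration.

Latent time-course construction: i.i.d. Gaussian noise is low-pass
filtered, empirically whitened, and multiplied by a symmetric square
root of the target correlation matrix, so the *empirical* correlation of
the series equals the target exactly even at short scan lengths.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import child_seed
from .design import StudyDesign, write_design
from .matching import TemplateSet, write_templates
from .preprocess import ConfoundMatrix, lowpass_filter, write_confounds
from .volume import Volume4D, write_mask, write_volume4d

__all__ = [
    "SyntheticTruth",
    "make_templates",
    "make_study_space",
    "sample_network_timecourses",
    "synthesize_subject",
    "synthesize_study",
    "jitter_correlation",
    "gaussian_loadings",
    "default_group_correlations",
    "default_truth",
]

DEFAULT_NETWORK_NAMES = ("DMN", "CEN", "CAN", "SN", "AN")


# ---------------------------------------------------------------------------
# spatial structure

def _sphere(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    g = np.mgrid[-r: r + 1, -r: r + 1, -r: r + 1]
    return (g**2).sum(axis=0) <= radius**2


def _ellipsoid_mask(grid: tuple[int, int, int], margin: float = 1.0) -> np.ndarray:
    """Brain stand-in: an ellipsoid inset from the grid boundary."""
    idx = np.indices(grid).astype(float)
    out = np.zeros(grid, dtype=bool)
    centers = [(g - 1) / 2.0 for g in grid]
    radii = [max((g - 1) / 2.0 - margin, 1.0) for g in grid]
    d = sum(
        ((idx[i] - centers[i]) / radii[i]) ** 2 for i in range(3)
    )
    out[d <= 1.0] = True
    return out


def make_templates(
    grid: tuple[int, int, int],
    k: int,
    blob_radius: float = 3.0,
    seed: int = 0,
    names: list[str] | None = None,
    max_overlap: float = 0.0,
    brain_mask: np.ndarray | None = None,
    max_tries: int = 5000,
) -> TemplateSet:
    """Place ``k`` thresholded Gaussian-blob masks inside the brain mask.

    Blobs are spheres of ``blob_radius`` voxels placed at random centers;
    placement retries until pairwise overlap stays within ``max_overlap``
    (default: fully disjoint). Deterministic given ``seed``.
    """
    if names is None:
        base = list(DEFAULT_NETWORK_NAMES)
        names = [base[i] if i < len(base) else f"NET{i}" for i in range(k)]
    if len(names) != k:
        raise ValueError("need one name per template")
    if brain_mask is None:
        brain_mask = _ellipsoid_mask(grid)
    rng = np.random.default_rng(seed)
    sphere = _sphere(blob_radius)
    # valid centers: sphere fits entirely inside the brain mask
    valid = ndimage.binary_erosion(brain_mask, structure=sphere, border_value=0)
    centers = np.argwhere(valid)
    if centers.size == 0:
        raise ValueError("blob radius too large for the brain mask")
    r = int(np.ceil(blob_radius))

    def blob_at(center: np.ndarray) -> np.ndarray:
        cx, cy, cz = center
        cand = np.zeros(grid, dtype=bool)
        cand[cx - r: cx + r + 1, cy - r: cy + r + 1, cz - r: cz + r + 1] = sphere
        return cand

    masks: list[np.ndarray] = []
    for _ in range(max(1, max_tries // max(k, 1))):
        masks = []
        avail = centers.copy()
        rng.shuffle(avail)
        while len(masks) < k and len(avail):
            cand = blob_at(avail[0])
            ok = all(
                (cand & m).sum() / min(cand.sum(), m.sum()) <= max_overlap
                for m in masks
            )
            if ok:
                masks.append(cand)
                # prune centers whose blob would certainly overlap too much
                dist = np.linalg.norm(avail - avail[0], axis=1)
                avail = avail[dist > (2 * blob_radius if max_overlap == 0 else 0)]
            else:
                avail = avail[1:]
        if len(masks) == k:
            break
    if len(masks) < k:
        raise ValueError(
            f"cannot place {k} blobs with overlap <= {max_overlap} "
            f"after {max_tries} tries"
        )
    return TemplateSet(
        names=list(names), masks=masks, brain_mask=brain_mask, max_overlap=max_overlap
    )


def make_study_space(
    grid: tuple[int, int, int],
    k: int,
    blob_radius: float = 3.0,
    seed: int = 0,
    names: list[str] | None = None,
) -> tuple[TemplateSet, np.ndarray, np.ndarray]:
    """Templates plus disjoint white-matter and CSF blobs in one brain.

    Returns ``(templates, wm_mask, csf_mask)``; all ``k + 2`` blobs are
    pairwise disjoint so tissue signals never mix with network signals.
    """
    if names is None:
        base = list(DEFAULT_NETWORK_NAMES)
        names = [base[i] if i < len(base) else f"NET{i}" for i in range(k)]
    full = make_templates(
        grid, k + 2, blob_radius=blob_radius, seed=seed,
        names=[*names, "WM", "CSF"],
    )
    templates = TemplateSet(
        names=full.names[:k], masks=full.masks[:k], brain_mask=full.brain_mask
    )
    return templates, full.masks[k], full.masks[k + 1]


def gaussian_loadings(templates: TemplateSet, sigma: float = 1.0) -> list[np.ndarray]:
    """Smooth in-mask loading maps (max 1), supported within each template."""
    loadings = []
    for mask in templates.masks:
        smooth = ndimage.gaussian_filter(mask.astype(float), sigma=sigma)
        smooth *= mask
        loadings.append(smooth / smooth.max())
    return loadings


# ---------------------------------------------------------------------------
# latent time courses

def _check_correlation(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    K = corr.shape[0]
    if corr.shape != (K, K) or not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be square symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(corr)
    if lam[0] < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {lam[0]:.3g})"
        )
    return corr


def _symmetric_sqrt(corr: np.ndarray) -> np.ndarray:
    lam, vec = np.linalg.eigh(corr)
    lam = np.clip(lam, 0.0, None)
    return (vec * np.sqrt(lam)) @ vec.T


def sample_network_timecourses(
    t_points: int,
    tr_seconds: float,
    corr: np.ndarray,
    lowfreq_cutoff_hz: float = 0.08,
    seed: int = 0,
    orthogonalize_to: np.ndarray | None = None,
) -> np.ndarray:
    """Draw a ``(T, K)`` latent matrix with exact empirical correlation.

    Columns have zero mean and unit (population) variance; spectral power
    is confined below ``lowfreq_cutoff_hz``. The filtered noise is
    empirically decorrelated before the target square root is applied, so
    ``np.corrcoef`` of the output reproduces ``corr`` exactly.

    ``orthogonalize_to`` (a ``(T, C)`` nuisance matrix) projects the
    series out of the span of the *band-limited part* of those columns
    before decorrelation; with a brick-wall filter this makes the output
    exactly orthogonal to the full nuisance series, so downstream
    confound regression cannot disturb the planted correlations.
    """
    corr = _check_correlation(corr)
    K = corr.shape[0]
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((t_points, K))
    Y = lowpass_filter(raw, tr_seconds, lowfreq_cutoff_hz)
    Y = Y - Y.mean(axis=0, keepdims=True)
    if orthogonalize_to is not None:
        X = np.atleast_2d(np.asarray(orthogonalize_to, dtype=float))
        X = lowpass_filter(X, tr_seconds, lowfreq_cutoff_hz)
        X = X - X.mean(axis=0, keepdims=True)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        Y = Y - X @ beta
    C = (Y.T @ Y) / t_points
    lam, vec = np.linalg.eigh(C)
    if lam[0] < 1e-10 * lam[-1]:
        raise ValueError(
            "filtered noise is rank deficient: too few retained frequencies "
            f"for {K} series at T={t_points}"
        )
    whiten = (vec / np.sqrt(lam)) @ vec.T
    Z = (Y @ whiten) @ _symmetric_sqrt(corr)
    return Z


def jitter_correlation(
    corr: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Subject-level correlation matrix: group mean plus symmetric noise.

    Off-diagonal Gaussian perturbations are symmetrized, eigenvalues are
    clipped to stay positive semi-definite, and the diagonal is
    renormalized to 1.
    """
    corr = np.asarray(corr, dtype=float)
    K = corr.shape[0]
    noise = rng.normal(0.0, sd, size=(K, K))
    noise = (noise + noise.T) / np.sqrt(2.0)
    np.fill_diagonal(noise, 0.0)
    c = corr + noise
    lam, vec = np.linalg.eigh(c)
    lam = np.clip(lam, 1e-4, None)
    c = (vec * lam) @ vec.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


# ---------------------------------------------------------------------------
# subjects and studies

def synthesize_subject(
    templates: TemplateSet,
    timecourses: np.ndarray,
    noise_sd: float = 0.0,
    confounds: np.ndarray | None = None,
    confound_weights: list[np.ndarray] | None = None,
    seed: int = 0,
    maps: list[np.ndarray] | None = None,
    tr_seconds: float = 2.0,
) -> Volume4D:
    """Compose one subject's 4D volume from planted structure.

    In-mask signal is ``sum_k map_k * tc_k(t) + sum_c weight_c * conf_c(t)``
    plus i.i.d. Gaussian noise of SD ``noise_sd``. ``maps`` defaults to
    the binary template masks.
    """
    timecourses = np.asarray(timecourses, dtype=float)
    T, K = timecourses.shape
    if K != len(templates):
        raise ValueError(
            f"{K} time courses for {len(templates)} templates"
        )
    if maps is None:
        maps = [m.astype(float) for m in templates.masks]
    brain = templates.brain_mask
    grid = brain.shape
    for m in maps:
        if m.shape != grid:
            raise ValueError("map grid mismatch")
    V = int(brain.sum())
    M = np.vstack([m[brain] for m in maps])  # K x V
    data_in = timecourses @ M  # T x V
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.shape[0] != T:
            raise ValueError("confound rows must match time points")
        C = confounds.shape[1]
        if confound_weights is None or len(confound_weights) != C:
            raise ValueError("need one spatial weight map per confound")
        W = np.vstack([np.asarray(w, float)[brain] for w in confound_weights])
        data_in = data_in + confounds @ W
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data_in = data_in + rng.normal(0.0, noise_sd, size=(T, V))
    data = np.zeros(grid + (T,))
    data[brain] = data_in.T
    return Volume4D(data=data, tr_seconds=tr_seconds, mask=brain)


def default_group_correlations(
    names: list[str] | tuple[str, ...] = DEFAULT_NETWORK_NAMES,
) -> dict[str, np.ndarray]:
    """Group correlation matrices following the planted effect pattern.

    The control group couples the affective network to the executive,
    attention, and salience networks more strongly than the depressed
    group (0.30 vs 0.15, -0.39 vs -0.22, -0.18 vs -0.02); a common
    default-mode/executive edge of 0.40 is shared.
    """
    names = list(names)
    K = len(names)
    idx = {n: i for i, n in enumerate(names)}

    def build(edges: dict[tuple[str, str], float]) -> np.ndarray:
        c = np.eye(K)
        for (a, b), r in edges.items():
            if a in idx and b in idx:
                c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
        return c

    control = build(
        {("AN", "CEN"): 0.30, ("AN", "CAN"): -0.39, ("AN", "SN"): -0.18,
         ("DMN", "CEN"): 0.40}
    )
    depressed = build(
        {("AN", "CEN"): 0.15, ("AN", "CAN"): -0.22, ("AN", "SN"): -0.02,
         ("DMN", "CEN"): 0.40}
    )
    for c in (control, depressed):
        _check_correlation(c)
    return {"control": control, "depressed": depressed}


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a study and score recovery.

    ``corr_by_group`` maps each design group label to its K x K latent
    correlation matrix; ``behavior_beta1`` links the chosen edge's
    per-subject correlation to the executive score (negative by default
    to plant an inverse association).
    """

    template_names: list[str]
    template_masks: list[np.ndarray]
    brain_mask: np.ndarray
    wm_mask: np.ndarray | None
    csf_mask: np.ndarray | None
    maps: list[np.ndarray]
    corr_by_group: dict[str, np.ndarray]
    noise_sd: float = 0.5
    subject_corr_sd: float = 0.0
    n_motion_confounds: int = 6
    motion_confound_strength: float = 0.0
    behavior_edge: tuple[int, int] = (3, 4)
    behavior_beta0: float = 0.0
    behavior_beta1: float = -1.0
    behavior_noise_sd: float = 0.2
    tr_seconds: float = 2.0
    lowfreq_cutoff_hz: float = 0.07

    def __post_init__(self) -> None:
        for g, c in self.corr_by_group.items():
            self.corr_by_group[g] = _check_correlation(np.asarray(c, float))
        for m in self.maps:
            if np.asarray(m).shape != self.brain_mask.shape:
                raise ValueError("truth map grid mismatch")
        for m, mask in zip(self.maps, self.template_masks):
            if np.any(np.asarray(m)[~np.asarray(mask, bool)] != 0):
                raise ValueError("truth maps must be supported within templates")

    @property
    def n_networks(self) -> int:
        return len(self.template_names)

    def templates(self) -> TemplateSet:
        return TemplateSet(
            names=list(self.template_names),
            masks=list(self.template_masks),
            brain_mask=self.brain_mask,
        )

    def to_json_dict(self) -> dict:
        return {
            "template_names": list(self.template_names),
            "template_masks": [np.asarray(m, int).tolist() for m in self.template_masks],
            "brain_mask": np.asarray(self.brain_mask, int).tolist(),
            "wm_mask": None if self.wm_mask is None else np.asarray(self.wm_mask, int).tolist(),
            "csf_mask": None if self.csf_mask is None else np.asarray(self.csf_mask, int).tolist(),
            "maps": [np.asarray(m, float).tolist() for m in self.maps],
            "corr_by_group": {g: c.tolist() for g, c in self.corr_by_group.items()},
            "noise_sd": self.noise_sd,
            "subject_corr_sd": self.subject_corr_sd,
            "n_motion_confounds": self.n_motion_confounds,
            "motion_confound_strength": self.motion_confound_strength,
            "behavior_edge": list(self.behavior_edge),
            "behavior_beta0": self.behavior_beta0,
            "behavior_beta1": self.behavior_beta1,
            "behavior_noise_sd": self.behavior_noise_sd,
            "tr_seconds": self.tr_seconds,
            "lowfreq_cutoff_hz": self.lowfreq_cutoff_hz,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            template_names=list(d["template_names"]),
            template_masks=[np.asarray(m, bool) for m in d["template_masks"]],
            brain_mask=np.asarray(d["brain_mask"], bool),
            wm_mask=None if d["wm_mask"] is None else np.asarray(d["wm_mask"], bool),
            csf_mask=None if d["csf_mask"] is None else np.asarray(d["csf_mask"], bool),
            maps=[np.asarray(m, float) for m in d["maps"]],
            corr_by_group={g: np.asarray(c, float) for g, c in d["corr_by_group"].items()},
            noise_sd=float(d["noise_sd"]),
            subject_corr_sd=float(d["subject_corr_sd"]),
            n_motion_confounds=int(d["n_motion_confounds"]),
            motion_confound_strength=float(d["motion_confound_strength"]),
            behavior_edge=tuple(d["behavior_edge"]),
            behavior_beta0=float(d["behavior_beta0"]),
            behavior_beta1=float(d["behavior_beta1"]),
            behavior_noise_sd=float(d["behavior_noise_sd"]),
            tr_seconds=float(d["tr_seconds"]),
            lowfreq_cutoff_hz=float(d["lowfreq_cutoff_hz"]),
        )


def default_truth(
    grid: tuple[int, int, int] = (20, 20, 20),
    k: int = 5,
    blob_radius: float = 2.5,
    seed: int = 0,
    noise_sd: float = 0.5,
    subject_corr_sd: float = 0.27,
    motion_confound_strength: float = 0.3,
    group_names: tuple[str, str] = ("control", "depressed"),
    behavior_beta1: float = -1.0,
    behavior_noise_sd: float = 0.2,
) -> SyntheticTruth:
    """Default planted truth: 5 networks, two groups, behavior edge SN-AN."""
    templates, wm, csf = make_study_space(
        grid, k, blob_radius=blob_radius, seed=child_seed(seed, "space")
    )
    loadings = gaussian_loadings(templates)
    corr = default_group_correlations(templates.names)
    corr_by_group = {
        group_names[0]: corr["control"][:k, :k],
        group_names[1]: corr["depressed"][:k, :k],
    }
    idx = {n: i for i, n in enumerate(templates.names)}
    edge = (
        (idx["SN"], idx["AN"]) if "SN" in idx and "AN" in idx else (k - 2, k - 1)
    )
    edge = (min(edge), max(edge))
    return SyntheticTruth(
        template_names=templates.names,
        template_masks=templates.masks,
        brain_mask=templates.brain_mask,
        wm_mask=wm,
        csf_mask=csf,
        maps=loadings,
        corr_by_group=corr_by_group,
        noise_sd=noise_sd,
        subject_corr_sd=subject_corr_sd,
        motion_confound_strength=motion_confound_strength,
        behavior_edge=edge,
        behavior_beta1=behavior_beta1,
        behavior_noise_sd=behavior_noise_sd,
    )


def _smooth_series(
    rng: np.random.Generator, t_points: int, tr_seconds: float, cutoff_hz: float
) -> np.ndarray:
    """Standardized low-frequency random series (motion/tissue-like)."""
    s = lowpass_filter(
        rng.standard_normal(t_points), tr_seconds, cutoff_hz
    )
    s = s - s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


def _smooth_weight_map(
    rng: np.random.Generator, brain_mask: np.ndarray, strength: float
) -> np.ndarray:
    w = ndimage.gaussian_filter(rng.standard_normal(brain_mask.shape), sigma=2.0)
    w = w * brain_mask
    sd = w[brain_mask].std()
    return w * (strength / sd) if sd > 0 else w


def synthesize_study(
    design: StudyDesign,
    truth: SyntheticTruth,
    t_points: int = 150,
    out_dir: str | os.PathLike = ".",
    seed: int = 0,
) -> dict:
    """Write a full synthetic study directory and return its record.

    Per subject: a subject-level correlation matrix is drawn around the
    group matrix (SD ``truth.subject_corr_sd``), latent time courses are
    sampled with that exact empirical correlation, and the 4D volume is
    composed with confounds and noise. The executive score is generated
    as ``beta0 + beta1 * (chosen-edge correlation) + noise``. Everything
    is deterministic given ``seed`` and the truth record.
    """
    missing = [g for g in design.group_levels if g not in truth.corr_by_group]
    if missing:
        raise ValueError(f"design group(s) missing from truth: {missing}")
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    templates = truth.templates()
    write_templates(templates, os.path.join(out_dir, "templates"))
    write_mask(truth.brain_mask, os.path.join(out_dir, "mask.nii"))
    if truth.wm_mask is not None:
        write_mask(truth.wm_mask, os.path.join(out_dir, "wm_mask.nii"))
    if truth.csf_mask is not None:
        write_mask(truth.csf_mask, os.path.join(out_dir, "csf_mask.nii"))

    subjects: dict[str, dict] = {}
    executive = np.zeros(len(design))
    depression = np.array(design.depression_score, dtype=float)
    i_edge, j_edge = truth.behavior_edge
    use_confounds = truth.motion_confound_strength > 0 and truth.n_motion_confounds > 0

    for s_idx, sid in enumerate(design.subject_ids):
        group = design.group[s_idx]
        sub_seed = child_seed(seed, f"subject:{sid}")
        rng = np.random.default_rng(sub_seed)
        corr = truth.corr_by_group[group]
        if truth.subject_corr_sd > 0:
            corr = jitter_correlation(corr, truth.subject_corr_sd, rng)
        confounds = None
        weights = None
        conf_names: list[str] = []
        series_list: list[np.ndarray] = []
        weight_list: list[np.ndarray] = []
        if use_confounds:
            for c in range(truth.n_motion_confounds):
                series_list.append(
                    _smooth_series(rng, t_points, truth.tr_seconds, 0.1)
                )
                weight_list.append(
                    _smooth_weight_map(
                        rng, truth.brain_mask, truth.motion_confound_strength
                    )
                )
                conf_names.append(f"motion{c}")
        if truth.wm_mask is not None and use_confounds:
            series_list.append(
                _smooth_series(rng, t_points, truth.tr_seconds, 0.1)
            )
            weight_list.append(truth.wm_mask.astype(float))
            conf_names.append("wm_source")
        if truth.csf_mask is not None and use_confounds:
            series_list.append(
                _smooth_series(rng, t_points, truth.tr_seconds, 0.1)
            )
            weight_list.append(truth.csf_mask.astype(float))
            conf_names.append("csf_source")
        if series_list:
            confounds = np.column_stack(series_list)
            weights = weight_list
        # latent series are sampled orthogonal to the confounds so that
        # downstream nuisance regression preserves the planted correlations
        tcs = sample_network_timecourses(
            t_points,
            truth.tr_seconds,
            corr,
            lowfreq_cutoff_hz=truth.lowfreq_cutoff_hz,
            seed=child_seed(sub_seed, "timecourses"),
            orthogonalize_to=confounds,
        )
        vol = synthesize_subject(
            templates,
            tcs,
            noise_sd=truth.noise_sd,
            confounds=confounds,
            confound_weights=weights,
            seed=child_seed(sub_seed, "noise"),
            maps=truth.maps,
            tr_seconds=truth.tr_seconds,
        )
        write_volume4d(vol, os.path.join(out_dir, f"sub-{sid}.nii"))
        # the confound TSV carries the motion-like regressors only; tissue
        # signals are re-extracted from the data during preprocessing
        if use_confounds:
            motion_cols = [
                i for i, n in enumerate(conf_names) if n.startswith("motion")
            ]
            write_confounds(
                ConfoundMatrix(
                    values=confounds[:, motion_cols],
                    names=[conf_names[i] for i in motion_cols],
                ),
                os.path.join(out_dir, f"sub-{sid}_confounds.tsv"),
            )
        edge_r = float(corr[i_edge, j_edge])
        executive[s_idx] = (
            truth.behavior_beta0
            + truth.behavior_beta1 * edge_r
            + rng.normal(0.0, truth.behavior_noise_sd)
        )
        depression[s_idx] = max(
            0.0,
            rng.normal(7.0, 9.2) if group != design.group_levels[0] else abs(rng.normal(0.0, 0.9)),
        )
        subjects[sid] = {
            "group": str(group),
            "corr": np.round(corr, 10).tolist(),
            "edge_r": edge_r,
            "seed": int(sub_seed),
        }

    gen_design = StudyDesign(
        subject_ids=design.subject_ids,
        group=design.group,
        age=design.age,
        depression_score=depression,
        executive_score=executive,
    )
    write_design(gen_design, os.path.join(out_dir, "design.tsv"))

    record = {
        "seed": int(seed),
        "t_points": int(t_points),
        "truth": truth.to_json_dict(),
        "subjects": subjects,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(record, fh)
    return record


def load_truth_record(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        record = json.load(fh)
    record["truth_obj"] = SyntheticTruth.from_json_dict(record["truth"])
    return record
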