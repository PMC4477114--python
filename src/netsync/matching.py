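"""Goodness-of-fit assignment of components to named network templates.

The score for a component against a binary template is the mean z value
inside the template minus the mean z outside it (within the brain mask),
so it is invariant to adding a constant to the map and scales linearly
with the map. Each template takes the best-scoring component; a close
second is retained as a component of interest as well.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import read_mask, write_mask

__all__ = [
    "TemplateSet",
    "ComponentAssignment",
    "goodness_of_fit",
    "match_components",
    "read_templates",
    "write_templates",
    "threshold_template",
]

CANONICAL_NETWORK_NAMES = ("DMN", "CEN", "CAN", "SN", "AN")


@dataclass
class TemplateSet:
    """Named binary network templates on a common grid.

    Each mask must be nonempty and a strict subset of the brain mask;
    pairwise overlap is limited to ``max_overlap`` fraction of the smaller
    mask (default 0: disjoint).
    """

    names: list[str]
    masks: list[np.ndarray]
    brain_mask: np.ndarray
    max_overlap: float = 0.0

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        if len(self.names) != len(self.masks):
            raise ValueError("names and masks length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("template names must be unique")
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        self.masks = [np.asarray(m).astype(bool) for m in self.masks]
        for name, m in zip(self.names, self.masks):
            if m.shape != self.brain_mask.shape:
                raise ValueError(f"template {name!r}: grid mismatch")
            if not m.any():
                raise ValueError(f"template {name!r} is empty")
            if (m & ~self.brain_mask).any() or m.sum() >= self.brain_mask.sum():
                raise ValueError(
                    f"template {name!r} is not strictly inside the brain mask"
                )
        for i in range(len(self.masks)):
            for j in range(i + 1, len(self.masks)):
                smaller = min(self.masks[i].sum(), self.masks[j].sum())
                overlap = (self.masks[i] & self.masks[j]).sum() / smaller
                if overlap > self.max_overlap:
                    raise ValueError(
                        f"templates {self.names[i]!r} and {self.names[j]!r} "
                        f"overlap by {overlap:.2f} > {self.max_overlap}"
                    )

    def __len__(self) -> int:
        return len(self.masks)


@dataclass
class ComponentAssignment:
    """One template's match: best component, all scores, optional second."""

    network_name: str
    primary_component: int
    gof_scores: np.ndarray
    secondary_component: int | None = None
    no_credible_match: bool = False

    def __post_init__(self) -> None:
        self.gof_scores = np.asarray(self.gof_scores, dtype=float)
        if self.primary_component != int(np.argmax(self.gof_scores)):
            raise ValueError("primary_component must be the argmax of gof_scores")


def goodness_of_fit(
    zmap: np.ndarray, template: np.ndarray, brain_mask: np.ndarray
) -> float:
    """Mean z inside the template minus mean z outside (within brain mask)."""
    zmap = np.asarray(zmap, dtype=float)
    template = np.asarray(template).astype(bool)
    brain_mask = np.asarray(brain_mask).astype(bool)
    inside = template & brain_mask
    outside = brain_mask & ~template
    if not inside.any():
        raise ValueError("template is empty within the brain mask")
    if not outside.any():
        raise ValueError("template covers the whole brain mask")
    return float(zmap[inside].mean() - zmap[outside].mean())


def match_components(
    ics, templates: TemplateSet, close_ratio: float = 0.9
) -> list[ComponentAssignment]:
    """Assign each template its best-GOF component; keep close seconds.

    For each template the primary component is the GOF argmax (ties break
    to the lowest component index); the secondary is retained iff the
    second-best GOF is at least ``close_ratio`` times the best and the
    best is positive. Templates whose scores are all non-positive are
    flagged ``no_credible_match`` with a warning. Components may serve
    multiple templates.
    """
    K = ics.n_components
    if K < 1 or len(templates) < 1:
        raise ValueError("need at least one component and one template")
    assignments = []
    for name, tmpl in zip(templates.names, templates.masks):
        scores = np.array(
            [
                goodness_of_fit(ics.maps[..., k], tmpl, ics.mask)
                for k in range(K)
            ]
        )
        primary = int(np.argmax(scores))  # ties -> lowest index
        secondary = None
        flagged = False
        best = scores[primary]
        if best <= 0:
            flagged = True
            warnings.warn(
                f"template {name!r}: no credible match (all GOF <= 0)",
                stacklevel=2,
            )
        elif K > 1:
            rest = np.delete(np.arange(K), primary)
            second = int(rest[np.argmax(scores[rest])])
            if scores[second] >= close_ratio * best:
                secondary = second
        assignments.append(
            ComponentAssignment(
                network_name=name,
                primary_component=primary,
                gof_scores=scores,
                secondary_component=secondary,
                no_credible_match=flagged,
            )
        )
    return assignments


def threshold_template(zmap: np.ndarray, z_threshold: float = 1.0) -> np.ndarray:
    """Binarize a probabilistic/z-valued template at a threshold."""
    return np.asarray(zmap, dtype=float) > z_threshold


def assignments_to_frame(assignments: list[ComponentAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "network": [a.network_name for a in assignments],
            "component": [a.primary_component for a in assignments],
            "gof": [a.gof_scores[a.primary_component] for a in assignments],
            "secondary_component": [
                a.secondary_component if a.secondary_component is not None else ""
                for a in assignments
            ],
            "no_credible_match": [a.no_credible_match for a in assignments],
        }
    )


def gof_matrix_frame(assignments: list[ComponentAssignment]) -> pd.DataFrame:
    """Full GOF audit matrix: one row per template, one column per component."""
    K = len(assignments[0].gof_scores)
    return pd.DataFrame(
        np.vstack([a.gof_scores for a in assignments]),
        index=[a.network_name for a in assignments],
        columns=[f"IC{k}" for k in range(K)],
    )


def write_templates(templates: TemplateSet, out_dir: str | os.PathLike) -> None:
    """Write templates as NIfTI masks plus a names manifest TSV."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for name, mask in zip(templates.names, templates.masks):
        fname = f"template_{name}.nii"
        write_mask(mask, os.path.join(out_dir, fname))
        rows.append({"network": name, "file": fname})
    write_mask(templates.brain_mask, os.path.join(out_dir, "brain_mask.nii"))
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "names.tsv"), sep="\t", index=False
    )


def read_templates(
    template_dir: str | os.PathLike, max_overlap: float = 0.0
) -> TemplateSet:
    manifest = os.path.join(template_dir, "names.tsv")
    if not os.path.exists(manifest):
        raise FileNotFoundError(manifest)
    df = pd.read_csv(manifest, sep="\t")
    names = [str(n) for n in df["network"]]
    masks = [read_mask(os.path.join(template_dir, f)) for f in df["file"]]
    brain_mask = read_mask(os.path.join(template_dir, "brain_mask.nii"))
    return TemplateSet(
        names=names, masks=masks, brain_mask=brain_mask, max_overlap=max_overlap
    )
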