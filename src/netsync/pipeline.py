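"""End-to-end pipeline: preprocess -> group ICA -> match -> dual regression
-> network statistics -> behavior correlations.

Every stage persists its intermediates under the output directory and can
be re-run from them; the whole chain is deterministic given the config's
``rng_seed``.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .design import StudyDesign
from .dualreg import SubjectNetworkTimecourses, dual_regress
from .ica import GroupICs, concatenate_subjects, fit_spatial_ica
from .matching import (
    ComponentAssignment,
    TemplateSet,
    assignments_to_frame,
    gof_matrix_frame,
    match_components,
    read_templates,
)
from .preprocess import preprocess_subject, read_confounds
from .stats import (
    EdgeStat,
    behavior_edge_correlation,
    edge_group_test,
    fisher_z,
    inter_network_correlation,
    mc_cluster_correction,
    voxelwise_group_test,
)
from .volume import (
    Volume4D,
    read_mask,
    read_volume4d,
    write_maps4d,
    write_volume4d,
)

logger = logging.getLogger("netsync")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Bundle of everything the pipeline produced (also persisted on disk)."""

    config: PipelineConfig
    out_dir: str
    group_ics: GroupICs
    assignments: list[ComponentAssignment]
    timecourses: dict[str, SubjectNetworkTimecourses]
    edge_values: pd.DataFrame  # subjects x edges (network-pair columns)
    edge_stats: list[EdgeStat]
    edge_stats_adjusted: list[EdgeStat]
    clusters: list
    behavior: pd.DataFrame
    voxelwise: dict


def _subject_paths(data_dir: str, design: StudyDesign) -> dict[str, str]:
    return {
        sid: os.path.join(data_dir, f"sub-{sid}.nii") for sid in design.subject_ids
    }


def _edge_list(n_networks: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_networks) for j in range(i + 1, n_networks)]


def network_stats_stage(
    config: PipelineConfig,
    design: StudyDesign,
    assignments: list[ComponentAssignment],
    timecourses: dict[str, SubjectNetworkTimecourses],
    out_dir: str | os.PathLike,
):
    """Edge statistics, cluster correction, and behavior correlations.

    Consumes the matched components and per-subject time courses; writes
    ``netstats/`` under ``out_dir`` and returns the in-memory results.
    """
    out_dir = str(out_dir)
    ns_dir = os.path.join(out_dir, "netstats")
    os.makedirs(ns_dir, exist_ok=True)
    network_names = [a.network_name for a in assignments]
    network_comps = [a.primary_component for a in assignments]
    edges = _edge_list(len(network_names))
    edge_cols = [f"{network_names[i]}-{network_names[j]}" for i, j in edges]

    rows = []
    for sid in design.subject_ids:
        inc = inter_network_correlation(
            timecourses[sid], store_fisher=config.fisher_z
        )
        sub = inc.r[np.ix_(network_comps, network_comps)]
        if config.fisher_z:
            sub = fisher_z(sub)
        rows.append([sub[i, j] for i, j in edges])
    edge_values = pd.DataFrame(rows, index=design.subject_ids, columns=edge_cols)
    edge_values.to_csv(os.path.join(ns_dir, "subject_edge_values.csv"))

    levels = design.group_levels
    if len(levels) != 2:
        raise RuntimeError(
            f"stage netstats: need exactly 2 groups, got {levels}"
        )
    idx_a = design.indices_of(levels[0])
    idx_b = design.indices_of(levels[1])
    vals = edge_values.to_numpy()
    edge_stats, edge_stats_adj = [], []
    for e_idx, (i, j) in enumerate(edges):
        name = (network_names[i], network_names[j])
        edge_stats.append(
            edge_group_test(
                vals[idx_a, e_idx], vals[idx_b, e_idx], edge=(i, j), edge_name=name
            )
        )
        edge_stats_adj.append(
            edge_group_test(
                vals[idx_a, e_idx],
                vals[idx_b, e_idx],
                age_a=design.age[idx_a],
                age_b=design.age[idx_b],
                edge=(i, j),
                edge_name=name,
            )
        )

    labels_a = np.array([g == levels[0] for g in design.group])
    try:
        clusters = mc_cluster_correction(
            edge_stats,
            vals,
            labels_a,
            n_sims=config.n_mc_sims,
            edge_alpha=config.edge_alpha,
            seed=config.child_seed("mc-cluster"),
        )
    except Exception as exc:
        raise RuntimeError(f"stage netstats (cluster correction): {exc}") from exc

    cluster_of_edge = {}
    for c_idx, cl in enumerate(clusters):
        for e in cl.edges:
            cluster_of_edge[e] = (c_idx, cl.p_corrected)
    stat_rows = []
    for st, st_adj in zip(edge_stats, edge_stats_adj):
        c_idx, p_corr = cluster_of_edge.get(st.edge, (None, None))
        stat_rows.append(
            {
                "edge": f"{st.edge_name[0]}-{st.edge_name[1]}",
                f"mean_{levels[0]}": st.mean_a,
                f"sd_{levels[0]}": st.sd_a,
                f"mean_{levels[1]}": st.mean_b,
                f"sd_{levels[1]}": st.sd_b,
                "t": st.t,
                "df": st.df,
                "p": st.p,
                "t_age_adjusted": st_adj.t,
                "p_age_adjusted": st_adj.p,
                "cluster": c_idx if c_idx is not None else "",
                "p_corrected": p_corr if p_corr is not None else "",
            }
        )
    pd.DataFrame(stat_rows).to_csv(
        os.path.join(ns_dir, "edge_stats.csv"), index=False
    )
    with open(os.path.join(ns_dir, "clusters.json"), "w") as fh:
        json.dump(
            [
                {
                    "edges": [
                        f"{network_names[i]}-{network_names[j]}" for i, j in cl.edges
                    ],
                    "size": cl.size,
                    "p_corrected": cl.p_corrected,
                    "null_sizes": cl.null_sizes,
                }
                for cl in clusters
            ],
            fh,
            indent=2,
        )

    behavior_rows = []
    score_cols = {
        "depression_score": design.depression_score,
        "executive_score": design.executive_score,
    }
    group_subsets = {"all": np.arange(len(design))}
    for g in levels:
        group_subsets[g] = design.indices_of(g)
    for score_name, scores in score_cols.items():
        for subset_name, subset in group_subsets.items():
            if len(subset) < 3:
                continue
            for e_idx, col in enumerate(edge_cols):
                x = vals[subset, e_idx]
                y = np.asarray(scores)[subset]
                if x.std() == 0 or y.std() == 0:
                    continue
                r, p = behavior_edge_correlation(x, y)
                behavior_rows.append(
                    {
                        "score": score_name,
                        "subset": subset_name,
                        "edge": col,
                        "r": r,
                        "p": p,
                        "n": len(subset),
                    }
                )
    behavior = pd.DataFrame(behavior_rows)
    behavior.to_csv(os.path.join(ns_dir, "behavior.csv"), index=False)
    return edge_values, edge_stats, edge_stats_adj, clusters, behavior


def run_pipeline(
    config: PipelineConfig,
    data_dir: str | os.PathLike,
    design: StudyDesign,
    out_dir: str | os.PathLike,
    templates_dir: str | os.PathLike | None = None,
) -> PipelineResult:
    """Run all stages on a flat study directory.

    Expects ``sub-<id>.nii`` per design row, optional
    ``sub-<id>_confounds.tsv``, optional ``mask.nii`` / ``wm_mask.nii`` /
    ``csf_mask.nii``, and a template directory (default
    ``<data_dir>/templates``). All subject files are checked before any
    computation starts.
    """
    data_dir = str(data_dir)
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    config.save(os.path.join(out_dir, "config.yaml"))

    paths = _subject_paths(data_dir, design)
    missing = [sid for sid, p in paths.items() if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(
            f"missing 4D file(s) for subject(s): {missing}"
        )
    if templates_dir is None:
        templates_dir = os.path.join(data_dir, "templates")
    templates = read_templates(templates_dir)

    mask_path = os.path.join(data_dir, "mask.nii")
    mask = read_mask(mask_path) if os.path.exists(mask_path) else None
    wm_path = os.path.join(data_dir, "wm_mask.nii")
    wm_mask = read_mask(wm_path) if os.path.exists(wm_path) else None
    csf_path = os.path.join(data_dir, "csf_mask.nii")
    csf_mask = read_mask(csf_path) if os.path.exists(csf_path) else None

    # --- preprocessing ------------------------------------------------
    pre_dir = os.path.join(out_dir, "preprocessed")
    os.makedirs(pre_dir, exist_ok=True)
    volumes: list[Volume4D] = []
    for sid in design.subject_ids:
        try:
            vol = read_volume4d(paths[sid], mask_path=None)
            if mask is not None:
                vol = Volume4D(data=vol.data, tr_seconds=vol.tr_seconds, mask=mask)
            config.validate_tr(vol.tr_seconds)
            conf_path = os.path.join(data_dir, f"sub-{sid}_confounds.tsv")
            confounds = read_confounds(conf_path) if os.path.exists(conf_path) else None
            vol = preprocess_subject(
                vol,
                confounds=confounds,
                wm_mask=wm_mask,
                csf_mask=csf_mask,
                cutoff_hz=config.lowpass_hz,
                filter_kind=config.filter_kind,
                filter_confounds_first=config.filter_confounds_first,
            )
            write_volume4d(vol, os.path.join(pre_dir, f"sub-{sid}.nii"))
            volumes.append(vol)
        except Exception as exc:
            raise RuntimeError(f"stage preprocess, subject {sid}: {exc}") from exc
    logger.info("preprocessed %d subjects", len(volumes))

    # --- group ICA ----------------------------------------------------
    try:
        concatenated = concatenate_subjects(volumes)
        ics = fit_spatial_ica(
            concatenated,
            n_components=config.n_components,
            mask=volumes[0].mask,
            seed=config.child_seed("ica"),
        )
    except Exception as exc:
        raise RuntimeError(f"stage ica: {exc}") from exc
    ica_dir = os.path.join(out_dir, "ica")
    ics.save(ica_dir)
    logger.info("fitted %d group components", ics.n_components)

    # --- template matching -------------------------------------------
    try:
        assignments = match_components(
            ics, templates, close_ratio=config.gof_close_ratio
        )
    except Exception as exc:
        raise RuntimeError(f"stage match: {exc}") from exc
    match_dir = os.path.join(out_dir, "match")
    os.makedirs(match_dir, exist_ok=True)
    assignments_to_frame(assignments).to_csv(
        os.path.join(match_dir, "assignments.csv"), index=False
    )
    gof_matrix_frame(assignments).to_csv(os.path.join(match_dir, "gof_matrix.csv"))

    # --- dual regression ----------------------------------------------
    dr_dir = os.path.join(out_dir, "dualreg")
    os.makedirs(dr_dir, exist_ok=True)
    timecourses: dict[str, SubjectNetworkTimecourses] = {}
    subject_maps = {}
    for sid, vol in zip(design.subject_ids, volumes):
        try:
            tcs, smaps = dual_regress(
                vol,
                ics,
                variance_normalize=config.variance_normalize_stage1,
                subject_id=sid,
            )
        except Exception as exc:
            raise RuntimeError(f"stage dualreg, subject {sid}: {exc}") from exc
        tcs.save(os.path.join(dr_dir, f"sub-{sid}_timecourses.tsv"))
        smaps.save(os.path.join(dr_dir, f"sub-{sid}_maps.nii"))
        timecourses[sid] = tcs
        subject_maps[sid] = smaps

    # --- network statistics -------------------------------------------
    edge_values, edge_stats, edge_stats_adj, clusters, behavior = network_stats_stage(
        config, design, assignments, timecourses, out_dir
    )
    idx_a = design.indices_of(design.group_levels[0])
    idx_b = design.indices_of(design.group_levels[1])

    # --- voxelwise group comparison per matched network ---------------
    voxelwise: dict[str, dict] = {}
    if config.run_voxelwise:
        vox_dir = os.path.join(out_dir, "netstats", "voxelwise")
        os.makedirs(vox_dir, exist_ok=True)
        for a in assignments:
            k = a.primary_component
            maps_a = [subject_maps[design.subject_ids[i]].maps[..., k] for i in idx_a]
            maps_b = [subject_maps[design.subject_ids[i]].maps[..., k] for i in idx_b]
            try:
                res = voxelwise_group_test(
                    maps_a,
                    maps_b,
                    mask=volumes[0].mask,
                    n_perm=config.n_perm_voxelwise,
                    cluster_z=config.cluster_z,
                    alpha=config.cluster_alpha,
                    seed=config.child_seed(f"voxelwise:{a.network_name}"),
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage netstats (voxelwise, {a.network_name}): {exc}"
                ) from exc
            write_maps4d(
                res.z_map[..., None],
                os.path.join(vox_dir, f"{a.network_name}_zmap.nii"),
            )
            voxelwise[a.network_name] = {
                "n_significant_clusters": len(res.clusters),
                "clusters": [
                    {k2: v for k2, v in c.items() if k2 != "voxels"}
                    for c in res.clusters
                ],
            }
        with open(os.path.join(vox_dir, "summary.json"), "w") as fh:
            json.dump(voxelwise, fh, indent=2)

    return PipelineResult(
        config=config,
        out_dir=out_dir,
        group_ics=ics,
        assignments=assignments,
        timecourses=timecourses,
        edge_values=edge_values,
        edge_stats=edge_stats,
        edge_stats_adjusted=edge_stats_adj,
        clusters=clusters,
        behavior=behavior,
        voxelwise=voxelwise,
    )
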