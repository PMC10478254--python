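"""End-to-end orchestration of the schizophrenia and control analysis arms.

The schizophrenia arm standardizes the stress panel, Ward-clusters the
cases, cuts the dendrogram at the rescaled-distance threshold, labels the
strata, contrasts panel genes and clinical categories between strata, and
runs the DEG → top-N → overrepresentation chain. The control arm mirrors
it, replacing the clustering step with the quartile stress-response index.

Every run writes deterministic TSV/JSON outputs plus a manifest (config
hash, seed, package version, per-stage row counts, no timestamps), so a
rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import differential_expression, overrepresentation, top_n
from .io import (
    DEATH_CATEGORIES,
    ExpressionMatrix,
    GenePanel,
    GeneSetCollection,
    SampleMetadata,
)
from .stats import ContingencyTable, fisher_exact_2x2, fisher_exact_rxc, mann_whitney_u
from .stratify import (
    cut_rescaled,
    label_strata,
    rescaled_heights,
    ward_cluster,
    zscore_standardize,
)
from .stress_index import IndexPanel, StressClass, stress_response_index

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and inputs for a pipeline run."""

    matrix: ExpressionMatrix
    metadata: SampleMetadata
    panel: GenePanel
    index_panel: IndexPanel | None = None
    gene_sets: GeneSetCollection | None = None
    out_dir: Path | str = "stresstrata_out"
    rescaled_cut: float = 20.0
    schedule: str = "incremental"
    top_n: int = 8000
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.rescaled_cut <= 25):
            raise ValueError("rescaled_cut must be in (0, 25]")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        self.out_dir = Path(self.out_dir)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.matrix.values.to_csv().encode())
        h.update(self.metadata.table.to_csv().encode())
        h.update(",".join(self.panel.symbols).encode())
        if self.index_panel is not None:
            h.update(",".join(self.index_panel.symbols).encode())
        if self.gene_sets is not None:
            for name, members in self.gene_sets.items():
                h.update(name.encode())
                h.update(",".join(sorted(members)).encode())
        h.update(
            f"{self.rescaled_cut}|{self.schedule}|{self.top_n}|{self.rng_seed}".encode()
        )
        return h.hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _panel_contrasts(
    matrix: ExpressionMatrix, panel: GenePanel, high: list[str], low: list[str]
) -> pd.DataFrame:
    rows = []
    mapping = panel.resolve(matrix.gene_ids)
    for symbol, gene in mapping.items():
        res = mann_whitney_u(
            matrix.values.loc[gene, high].to_numpy(),
            matrix.values.loc[gene, low].to_numpy(),
        )
        rows.append(
            {
                "gene": symbol,
                "mean_high": float(matrix.values.loc[gene, high].mean()),
                "mean_low": float(matrix.values.loc[gene, low].mean()),
                "u_statistic": res.statistic,
                "p_mwu": res.p_two_sided,
                "effect_size_r": res.effect_size_r,
            }
        )
    return pd.DataFrame(rows)


def _categorical_contrasts(
    meta: SampleMetadata, high: list[str], low: list[str]
) -> dict:
    """Fisher tests on cause-of-death (R×C) and family history (2×2)."""
    out: dict = {}
    tab = []
    for cat in DEATH_CATEGORIES:
        row = [
            sum(meta.table.loc[s, "death_category"] == cat for s in high),
            sum(meta.table.loc[s, "death_category"] == cat for s in low),
        ]
        tab.append(row)
    arr = np.asarray(tab)
    keep = arr.sum(axis=1) > 0
    if keep.sum() >= 2 and arr.sum() > 0:
        res = fisher_exact_rxc(ContingencyTable.from_array(arr[keep]))
        out["death_category_p"] = res.p_two_sided
    fh = meta.table["family_history"]
    h_known = [s for s in high if fh.loc[s] != "unknown"]
    l_known = [s for s in low if fh.loc[s] != "unknown"]
    tab2 = [
        [sum(fh.loc[s] == "present" for s in h_known), sum(fh.loc[s] == "absent" for s in h_known)],
        [sum(fh.loc[s] == "present" for s in l_known), sum(fh.loc[s] == "absent" for s in l_known)],
    ]
    if sum(map(sum, tab2)) > 0:
        res = fisher_exact_2x2(ContingencyTable.from_array(tab2))
        out["family_history_p"] = res.p_two_sided
        out["family_history_table"] = tab2
    return out


def _deg_chain(
    matrix: ExpressionMatrix,
    high: list[str],
    low: list[str],
    gene_sets: GeneSetCollection | None,
    n_top: int,
):
    groups = {s: 1 for s in high}
    groups.update({s: 2 for s in low})
    degs = differential_expression(matrix, groups)
    listed = top_n(degs, n_top)
    enrich = None
    if gene_sets is not None:
        universe = [r.gene for r in degs]
        enrich = overrepresentation(listed, gene_sets, universe, deg_records=degs)
    return degs, listed, enrich


def _deg_frame(degs) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"gene": r.gene, "t": r.t_statistic, "p": r.p, "log2fc": r.log2fc}
            for r in degs
        ]
    )
    return df.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)


def _enrich_frame(enrich) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "list_size": r.list_size,
                "universe_size": r.universe_size,
                "p": r.p_right_tail,
                "q_bh": r.q_bh,
                "overlap_genes": ",".join(r.overlap_genes),
            }
            for r in enrich
        ]
    )


def run_sz_arm(config: RunConfig) -> dict:
    """Stratify schizophrenia cases and contrast the resulting strata.

    Returns the run report (also written as JSON); writes the strata
    assignment, merge schedule, panel contrasts, DEG table and enrichment
    table under ``config.out_dir``.
    """
    config.metadata.require_match(config.matrix)
    sz = config.metadata.samples_where(diagnosis="SZ")
    if len(sz) < 4:
        raise ValueError("schizophrenia arm needs at least 4 SZ samples")
    sub = config.matrix.subset_samples(sz)

    std = zscore_standardize(sub, config.panel)
    dendro = ward_cluster(std)
    partition = cut_rescaled(dendro, config.rescaled_cut, config.schedule)
    labeling = label_strata(partition, std, config.panel)
    hsr = [s for s, lab in labeling.assignment.items() if lab == "HSR"]
    lsr = [s for s, lab in labeling.assignment.items() if lab == "LSR"]
    logger.info("stratification: %d HSR / %d LSR cases", len(hsr), len(lsr))

    contrasts = _panel_contrasts(sub, config.panel, hsr, lsr)
    categorical = _categorical_contrasts(config.metadata, hsr, lsr)
    degs, listed, enrich = _deg_chain(sub, hsr, lsr, config.gene_sets, config.top_n)

    out = config.out_dir
    assign_df = pd.DataFrame(
        {"sample": list(labeling.assignment), "stratum": list(labeling.assignment.values())}
    ).sort_values("sample", kind="mergesort")
    _write_tsv(assign_df, out / "sz_assignment.tsv")
    rs = rescaled_heights(dendro, config.schedule)
    sched_df = pd.DataFrame(
        {
            "step": np.arange(1, len(dendro.merges) + 1),
            "left": [m.left for m in dendro.merges],
            "right": [m.right for m in dendro.merges],
            "height_delta_sse": [m.height for m in dendro.merges],
            "rescaled": rs,
            "cluster_size": [m.size for m in dendro.merges],
        }
    )
    _write_tsv(sched_df, out / "sz_merge_schedule.tsv")
    _write_tsv(contrasts, out / "sz_panel_contrasts.tsv")
    _write_tsv(_deg_frame(degs), out / "sz_deg.tsv")
    if enrich is not None:
        _write_tsv(_enrich_frame(enrich), out / "sz_enrichment.tsv")

    report = {
        "arm": "SZ",
        "n_samples": len(sz),
        "n_hsr": len(hsr),
        "n_lsr": len(lsr),
        "concordance": {str(k): v for k, v in labeling.concordance.items()},
        "categorical": {
            k: v for k, v in categorical.items() if not isinstance(v, list)
        },
        "n_deg_tested": len(degs),
        "n_top": min(config.top_n, len(degs)),
        "top_enriched_set": enrich[0].set_name if enrich else None,
        "top_enriched_p": enrich[0].p_right_tail if enrich else None,
    }
    _write_json(report, out / "sz_report.json")
    _write_manifest(config, "sz", report, out / "sz_manifest.json")
    return report


def run_control_arm(config: RunConfig, sz_assignment: dict[str, str] | None = None) -> dict:
    """Classify controls by stress-response index and contrast the classes.

    Mirrors the schizophrenia arm with the quartile index in place of
    clustering; also writes the four-group contrast of the enriched-set
    genes (high/low stratum × diagnosis) when gene sets are provided.
    """
    if config.index_panel is None:
        raise ValueError("control arm requires an index panel")
    config.metadata.require_match(config.matrix)
    controls = config.metadata.samples_where(diagnosis="CONTROL")
    if len(controls) < 4:
        raise ValueError("control arm needs at least 4 control samples")
    sub = config.matrix.subset_samples(controls)

    indices = stress_response_index(sub, config.index_panel, controls)
    hsr = [s for s, r in indices.items() if r.stress_class is StressClass.HSR]
    lsr = [s for s, r in indices.items() if r.stress_class is StressClass.LSR]
    indet = [s for s, r in indices.items() if r.stress_class is StressClass.INDETERMINATE]
    if not hsr and not lsr:
        raise ValueError("all controls have indeterminate stress-response index")
    logger.info(
        "index classification: %d HSR / %d LSR / %d indeterminate controls",
        len(hsr), len(lsr), len(indet),
    )

    contrasts = _panel_contrasts(sub, config.panel, hsr, lsr)
    categorical = _categorical_contrasts(config.metadata, hsr, lsr)
    degs, listed, enrich = _deg_chain(sub, hsr, lsr, config.gene_sets, config.top_n)

    out = config.out_dir
    idx_df = pd.DataFrame(
        [
            {"sample": s, "score": r.score, "class": r.stress_class.value}
            for s, r in indices.items()
        ]
    ).sort_values("sample", kind="mergesort")
    _write_tsv(idx_df, out / "control_index.tsv")
    _write_tsv(contrasts, out / "control_panel_contrasts.tsv")
    _write_tsv(_deg_frame(degs), out / "control_deg.tsv")
    if enrich is not None:
        _write_tsv(_enrich_frame(enrich), out / "control_enrichment.tsv")
        _write_tsv(
            _four_group_contrasts(config, sz_assignment, hsr, lsr, enrich),
            out / "four_group_contrasts.tsv",
        )

    report = {
        "arm": "CONTROL",
        "n_samples": len(controls),
        "n_hsr": len(hsr),
        "n_lsr": len(lsr),
        "n_indeterminate": len(indet),
        "n_deg_tested": len(degs),
        "n_top": min(config.top_n, len(degs)),
        "top_enriched_set": enrich[0].set_name if enrich else None,
        "top_enriched_p": enrich[0].p_right_tail if enrich else None,
    }
    _write_json(report, out / "control_report.json")
    _write_manifest(config, "control", report, out / "control_manifest.json")
    return report


def _four_group_contrasts(
    config: RunConfig,
    sz_assignment: dict[str, str] | None,
    cont_hsr: list[str],
    cont_lsr: list[str],
    enrich,
) -> pd.DataFrame:
    """Per-gene comparisons of the top enriched set across the four strata."""
    if sz_assignment is None:
        sz = config.metadata.samples_where(diagnosis="SZ")
        sub = config.matrix.subset_samples(sz)
        std = zscore_standardize(sub, config.panel)
        dendro = ward_cluster(std)
        partition = cut_rescaled(dendro, config.rescaled_cut, config.schedule)
        sz_assignment = label_strata(partition, std, config.panel).assignment
    sz_hsr = [s for s, lab in sz_assignment.items() if lab == "HSR"]
    sz_lsr = [s for s, lab in sz_assignment.items() if lab == "LSR"]
    comparisons = {
        "HSR_SZ_vs_LSR_SZ": (sz_hsr, sz_lsr),
        "HSR_Cont_vs_LSR_Cont": (cont_hsr, cont_lsr),
        "HSR_SZ_vs_HSR_Cont": (sz_hsr, cont_hsr),
        "LSR_SZ_vs_LSR_Cont": (sz_lsr, cont_lsr),
    }
    genes = enrich[0].overlap_genes if enrich else []
    rows = []
    for gene in genes:
        for name, (a, b) in comparisons.items():
            if not a or not b:
                continue
            res = mann_whitney_u(
                config.matrix.values.loc[gene, a].to_numpy(),
                config.matrix.values.loc[gene, b].to_numpy(),
            )
            rows.append(
                {
                    "gene": gene,
                    "comparison": name,
                    "u_statistic": res.statistic,
                    "p_mwu": res.p_two_sided,
                    "effect_size_r": res.effect_size_r,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "comparison", "u_statistic", "p_mwu", "effect_size_r"])


def _write_manifest(config: RunConfig, arm: str, report: dict, path: Path) -> None:
    manifest = {
        "arm": arm,
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "rng_seed": config.rng_seed,
        "rescaled_cut": config.rescaled_cut,
        "schedule": config.schedule,
        "top_n": config.top_n,
        "stage_counts": {
            k: v for k, v in report.items() if isinstance(v, int)
        },
    }
    _write_json(manifest, path)
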