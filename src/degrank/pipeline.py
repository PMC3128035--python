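"""End-to-end orchestration: simulate -> preprocess -> rank -> truth ->
AUC / POG / correlation -> enrichment reproducibility.

Every emitted table is TSV; a JSON manifest records the configuration,
seed, produced list labels ("Method_Comparison_Site") and a SHA-256 digest
of each output file so a rerun can be checked for bit-identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as dio
from .enrichment import GeneSetCollection, enrichment_table, iu_table, rank_gene_sets
from .errors import DataError
from .evalmetrics import auc, cluster_lists, correlation_matrix, pog
from .matrix import ExpressionMatrix
from .preprocess import DEFAULT_FLOOR, clean_probe_gene_map, collapse_probes_to_genes, preprocess
from .ranking import METHODS, ClassDesign, compute_statistic, rank_genes, score_frame
from .synthetic import SimConfig, SimulatedStudy, simulate, write_study
from .truth import TruthSet, define_truth, require_nonempty

logger = logging.getLogger(__name__)

COMPARISONS = {"AB": ("A", "B"), "CD": ("C", "D")}
TRUTH_METRICS = {"FDR": ("fdr", 0.05), "AD": ("ad", 1.0)}
DEFAULT_X_GRID = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 200, 400, 800)


@dataclass
class RunBundle:
    outdir: Path
    manifest: dict


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g")


def default_x_grid(universe_size: int, grid=DEFAULT_X_GRID) -> list[int]:
    return [x for x in grid if x <= universe_size]


def run_full(
    config: SimConfig,
    outdir: str | Path,
    floor: float = DEFAULT_FLOOR,
    x_grid: tuple[int, ...] = DEFAULT_X_GRID,
) -> RunBundle:
    """Execute the whole study design on one synthetic dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("simulating study (seed=%d)", config.seed)
    study = simulate(config)
    write_study(study, outdir / "sim")

    processed = _preprocess_stage(study, outdir, floor)
    labels, probe_ranks_stable, probe_ranks_avg, scores_by_key = _ranking_stage(
        study, processed, outdir
    )
    truths = _truth_stage(study, outdir)
    auc_table = _auc_stage(study, scores_by_key, truths, outdir)
    pog_table = _pog_stage(study, probe_ranks_stable, x_grid, outdir)
    _correlation_stage(study, probe_ranks_avg, outdir)
    _enrichment_stage(study, processed, outdir)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "labels": labels,
        "files": {
            str(p.relative_to(outdir)): _digest(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("run complete: %d ranked lists", len(labels))
    return RunBundle(outdir, manifest)


def _preprocess_stage(
    study: SimulatedStudy, outdir: Path, floor: float
) -> dict[tuple[str, int], ExpressionMatrix]:
    processed = {}
    for (platform, site), raw in study.expression.items():
        mat = preprocess(raw, floor=floor, average_duplicates=True)
        processed[(platform, site)] = mat
        path = outdir / "processed" / f"{platform}_site{site}.tsv"
        path.parent.mkdir(parents=True, exist_ok=True)
        dio.write_expression(mat, path)
    return processed


def _ranking_stage(
    study: SimulatedStudy,
    processed: Mapping[tuple[str, int], ExpressionMatrix],
    outdir: Path,
):
    """Probe-level statistics for every method/comparison/site/platform."""
    labels: list[str] = []
    ranks_stable: dict[str, pd.Series] = {}
    ranks_avg: dict[str, pd.Series] = {}
    scores_by_key: dict[tuple, object] = {}
    for (platform, site), mat in processed.items():
        for comp, (t1, t2) in COMPARISONS.items():
            design = ClassDesign.from_samples(mat.samples.loc[list(mat.sample_ids)], t1, t2)
            for method in METHODS:
                table = compute_statistic(method, mat, design)
                label = f"{method}_{comp}_{site}"
                key = (platform, site, comp, method)
                scores_by_key[key] = table
                labels.append(f"{platform}:{label}")
                ranks_stable[f"{platform}:{label}"] = rank_genes(table, ties="stable")
                ranks_avg[f"{platform}:{label}"] = rank_genes(table, ties="average")
                _write_tsv(
                    score_frame(table),
                    outdir / "scores" / platform / f"{label}.tsv",
                )
    return labels, ranks_stable, ranks_avg, scores_by_key


def _truth_stage(study: SimulatedStudy, outdir: Path) -> dict[tuple[str, str], TruthSet]:
    truths = {}
    for comp, (t1, t2) in COMPARISONS.items():
        design = ClassDesign.from_samples(study.rtpcr.samples, t1, t2)
        for metric_label, (metric, threshold) in TRUTH_METRICS.items():
            name = f"RTPCR_{comp}_{metric_label}"
            ts = define_truth(study.rtpcr, design, metric, threshold, name=name)
            truths[(comp, metric_label)] = ts
            _write_tsv(ts.frame(), outdir / "truthsets" / f"{name}.tsv")
    return truths


def _auc_stage(study, scores_by_key, truths, outdir: Path) -> pd.DataFrame:
    """AUC per list per truth metric, with the across-site average, x100."""
    annotations = {p: l.annotation() for p, l in study.layouts.items()}
    rows = []
    for (platform, site, comp, method), table in scores_by_key.items():
        for (tcomp, metric_label), ts in truths.items():
            if tcomp != comp:
                continue
            try:
                value = auc(table, require_nonempty(ts), annotations[platform])
            except DataError:
                continue
            rows.append((platform, comp, metric_label, method, site, 100.0 * value))
    df = pd.DataFrame(
        rows, columns=["platform", "comparison", "metric", "method", "site", "auc"]
    )
    avg = (
        df.groupby(["platform", "comparison", "metric", "method"], sort=True)["auc"]
        .mean()
        .round(2)
        .rename("average_auc")
        .reset_index()
        .set_index("platform")
    )
    _write_tsv(df.set_index("platform"), outdir / "results" / "auc_per_site.tsv")
    _write_tsv(avg, outdir / "results" / "auc_average.tsv")
    return avg.reset_index()


def _pog_stage(study, ranks_stable, x_grid, outdir: Path) -> pd.DataFrame:
    """Across-site POG curves per platform/comparison/method."""
    rows = []
    for platform in study.layouts:
        sites = range(1, study.config.n_sites + 1)
        for comp in COMPARISONS:
            for method in METHODS:
                lists = [
                    ranks_stable[f"{platform}:{method}_{comp}_{s}"] for s in sites
                ]
                if len(lists) < 2:
                    continue
                for x in default_x_grid(len(lists[0]), x_grid):
                    rows.append(
                        (platform, comp, method, x, round(pog(lists, x), 4))
                    )
    df = pd.DataFrame(rows, columns=["platform", "comparison", "method", "X", "pog"])
    _write_tsv(df.set_index("platform"), outdir / "results" / "pog_genes.tsv")
    return df


def _correlation_stage(study, ranks_avg, outdir: Path) -> None:
    """Spearman matrices and average-linkage merge trees per platform."""
    for platform in study.layouts:
        lists = {
            label.split(":", 1)[1]: r
            for label, r in ranks_avg.items()
            if label.startswith(f"{platform}:")
        }
        rho = correlation_matrix(lists)
        _write_tsv(rho.round(6), outdir / "results" / f"spearman_{platform}.tsv")
        result = cluster_lists(lists)
        tree_path = outdir / "results" / f"cluster_{platform}.newick"
        tree_path.write_text(result.newick() + "\n")
        merge_df = pd.DataFrame(
            result.merges, columns=["left", "right", "height", "size"]
        )
        _write_tsv(merge_df, outdir / "results" / f"cluster_{platform}_merges.tsv")


def _enrichment_stage(study, processed, outdir: Path) -> None:
    """Gene-level ranks, E_G tables, set-level POG and IU ratios."""
    collection = GeneSetCollection(dict(study.gene_sets))
    config = study.config

    gene_ranks: dict[str, pd.Series] = {}  # "platform:method_comp_site"
    universes: dict[str, list[str]] = {}
    for (platform, site), mat in processed.items():
        ann = clean_probe_gene_map(study.layouts[platform].annotation())
        gene_mat = collapse_probes_to_genes(mat, ann)
        universes[platform] = list(gene_mat.probe_ids)
        for comp, (t1, t2) in COMPARISONS.items():
            design = ClassDesign.from_samples(
                gene_mat.samples.loc[list(gene_mat.sample_ids)], t1, t2
            )
            for method in METHODS:
                table = compute_statistic(method, gene_mat, design)
                gene_ranks[f"{platform}:{method}_{comp}_{site}"] = rank_genes(
                    table, ties="average"
                )

    set_rank_lists: dict[str, pd.Series] = {}
    for platform in study.layouts:
        restricted = collection.restrict(universes[platform])
        lists = {
            label.split(":", 1)[1]: r
            for label, r in gene_ranks.items()
            if label.startswith(f"{platform}:")
        }
        eg = enrichment_table(lists, restricted)
        _write_tsv(eg.round(4), outdir / "enrichment" / f"eg_{platform}.tsv")
        for label in eg.columns:
            set_rank_lists[f"{platform}:{label}"] = rank_gene_sets(eg[label])

    # set-level POG across sites (intra-platform)
    rows = []
    n_sets_min = min(len(r) for r in set_rank_lists.values())
    set_grid = [x for x in (5, 10, 20, 30, 50, 100, 186) if x <= n_sets_min]
    for platform in study.layouts:
        for comp in COMPARISONS:
            for method in METHODS:
                lists = [
                    set_rank_lists[f"{platform}:{method}_{comp}_{s}"]
                    for s in range(1, config.n_sites + 1)
                    if f"{platform}:{method}_{comp}_{s}" in set_rank_lists
                ]
                if len(lists) < 2:
                    continue
                for x in set_grid:
                    rows.append((platform, comp, method, x, round(pog(lists, x), 4)))
    df = pd.DataFrame(rows, columns=["platform", "comparison", "method", "X", "pog"])
    _write_tsv(df.set_index("platform"), outdir / "results" / "pog_gene_sets.tsv")

    # set-level POG across platforms (site 1 of each platform)
    rows = []
    platforms = list(study.layouts)
    if len(platforms) >= 2:
        for comp in COMPARISONS:
            for method in METHODS:
                lists = []
                for platform in platforms:
                    key = f"{platform}:{method}_{comp}_1"
                    if key in set_rank_lists:
                        lists.append(set_rank_lists[key])
                common = set(lists[0].index)
                for r in lists[1:]:
                    common &= set(r.index)
                lists = [r.loc[sorted(common)] for r in lists]
                # re-rank on the common set universe so POG is well defined
                lists = [
                    pd.Series(
                        np.argsort(np.argsort(r.to_numpy())) + 1.0, index=r.index
                    )
                    for r in lists
                ]
                if len(lists) < 2:
                    continue
                for x in [v for v in set_grid if v <= len(common)]:
                    rows.append((comp, method, x, round(pog(lists, x), 4)))
        df = pd.DataFrame(rows, columns=["comparison", "method", "X", "pog"])
        _write_tsv(
            df.set_index("comparison"),
            outdir / "results" / "pog_gene_sets_interplatform.tsv",
        )

    iu = iu_table(collection, universes)
    iu = iu.round(4)
    iu.loc["__mean__"] = iu["iu_ratio"].mean().round(4)
    _write_tsv(iu, outdir / "results" / "iu_ratio.tsv")


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(outdir: str | Path) -> str:
    """Markdown summary: best method per AUC cell and POG winners per X."""
    outdir = Path(outdir)
    auc_path = outdir / "results" / "auc_average.tsv"
    pog_path = outdir / "results" / "pog_genes.tsv"
    if not auc_path.exists() or not pog_path.exists():
        raise DataError(f"{outdir}: not a completed result bundle")
    avg = pd.read_csv(auc_path, sep="\t")
    pog_df = pd.read_csv(pog_path, sep="\t")

    lines = ["# Run summary", "", "## Best method per AUC cell", ""]
    lines.append("| platform | comparison | metric | best method(s) | AUC |")
    lines.append("|---|---|---|---|---|")
    for (platform, comp, metric), grp in avg.groupby(
        ["platform", "comparison", "metric"], sort=True
    ):
        best = grp[grp["average_auc"] == grp["average_auc"].max()]
        methods = ", ".join(sorted(best["method"]))
        lines.append(
            f"| {platform} | {comp} | {metric} | {methods} | {best['average_auc'].iloc[0]:.2f} |"
        )

    lines += ["", "## POG winners per X (across sites)", ""]
    lines.append("| platform | comparison | X | best method(s) | POG |")
    lines.append("|---|---|---|---|---|")
    for (platform, comp, x), grp in pog_df.groupby(
        ["platform", "comparison", "X"], sort=True
    ):
        best = grp[grp["pog"] == grp["pog"].max()]
        methods = ", ".join(sorted(best["method"]))
        lines.append(f"| {platform} | {comp} | {x} | {methods} | {best['pog'].iloc[0]:.1f} |")

    text = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(text)
    return text
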