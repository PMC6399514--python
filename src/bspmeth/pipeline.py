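"""End-to-end orchestration: islands -> convert -> call -> summarize ->
correlate -> TFBS scan -> report.

Every intermediate is written as TSV (re-readable by this package's own
readers) and the run closes with a JSON report reconciling record counts:
clones read = passed + failed, with per-clone failure reasons logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .association import flag_key_sites, pearson, significance_stars, site_correlation_table
from .calling import (
    integral_rate,
    lollipop_svg,
    lollipop_text,
    process_clones,
    summarize_group,
)
from .phenotype import compact_letters, ddct, one_way_anova, assign_stages, summarize_color, tukey_pairwise_p
from .reference import IslandParams, ReferenceRegion, bisulfite_convert, detect_cpg_islands, enumerate_cpg_sites
from .tfbs import default_motifs, load_motifs, overlap_cpg, scan_motifs

logger = logging.getLogger("bspmeth")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    reference_fasta: str
    clones_fasta: str
    manifest_tsv: str | None = None
    color_tsv: str | None = None
    ct_tsv: str | None = None
    motifs_yaml: str | None = None
    out_dir: str = "results"
    island_params: IslandParams = field(default_factory=IslandParams)
    min_conversion: float = 0.95
    min_identity: float = 0.90
    alpha: float = 0.05
    adjust: str = "none"
    calibrator_week: int | None = None  # default: smallest clone group label
    write_svg: bool = True

    def validate(self) -> None:
        for label, path in [
            ("reference", self.reference_fasta),
            ("clones", self.clones_fasta),
            ("manifest", self.manifest_tsv),
            ("color", self.color_tsv),
            ("ct", self.ct_tsv),
            ("motifs", self.motifs_yaml),
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label} input not found: {path}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the run report (also written as
    report.json in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ref_id, ref_seq = io.read_fasta(config.reference_fasta)[0]
    ref = ReferenceRegion(id=ref_id, sequence=ref_seq)

    # --- islands & sites -------------------------------------------------
    islands = detect_cpg_islands(ref, config.island_params)
    io.write_islands_bed(out / "islands.bed", ref.id, islands)
    if islands:
        target = max(islands, key=lambda i: i.length)
        interval = (target.start, target.end)
    else:
        logger.warning("no CpG island detected; using the whole reference")
        interval = (0, len(ref.sequence))
    sites = enumerate_cpg_sites(ref, interval)
    io.write_sites_tsv(out / "sites.tsv", sites)

    converted = bisulfite_convert(ref.sequence, "cpg_protected")

    # --- clone calling ---------------------------------------------------
    reads = io.read_clones(config.clones_fasta, config.manifest_tsv)
    matrices, qc = process_clones(
        reads, ref.sequence, converted, sites,
        config.min_conversion, config.min_identity,
    )
    qc.to_csv(out / "clone_qc.tsv", sep="\t", index=False)
    for _, row in qc[~qc["passed"]].iterrows():
        logger.info("excluded clone %s: %s", row["clone_id"], row["reason"])

    summaries = []
    meth_rows = {}
    for group_id in sorted(matrices, key=lambda g: (len(g), g)):
        matrix = matrices[group_id]
        io.write_call_matrix(out / f"calls_{group_id}.tsv", matrix)
        (out / f"lollipop_{group_id}.txt").write_text(lollipop_text(matrix))
        if config.write_svg:
            lollipop_svg(matrix, out / f"lollipop_{group_id}.svg")
        s = summarize_group(matrix)
        summaries.append(s)
        meth_rows[group_id] = s
    io.write_group_summaries(out / "methylation_summary.tsv", summaries)

    report: dict = {
        "version": __version__,
        "reference": ref.id,
        "n_islands": len(islands),
        "n_sites": len(sites),
        "clones": {
            "read": int(len(qc)),
            "passed": int(qc["passed"].sum()),
            "failed": int((~qc["passed"]).sum()),
        },
        "integral_rate_by_group": {
            g: s.integral_rate for g, s in meth_rows.items()
        },
    }

    # --- phenotype -------------------------------------------------------
    color_weekly = None
    if config.color_tsv:
        color = io.read_tsv(config.color_tsv)
        color_weekly = summarize_color(color)
        color_weekly.to_csv(out / "color_weekly.tsv", sep="\t")
        values_by_week = [
            grp[["r1", "r2", "r3"]].mean(axis=1).to_numpy()
            for _, grp in color.groupby("week")
        ]
        f, p = one_way_anova(values_by_week)
        letters = compact_letters(tukey_pairwise_p(values_by_week), config.alpha)
        stages = assign_stages(
            list(color_weekly.index), letters, list(color_weekly["mean"])
        )
        report["color"] = {
            "anova_F": f,
            "anova_p": p,
            "letters": dict(zip(map(str, color_weekly.index), letters)),
            "stages": [
                {"label": st.label, "weeks": list(st.weeks), "mean": st.mean}
                for st in stages
            ],
        }
        with open(out / "stages.json", "w") as fh:
            json.dump(report["color"], fh, indent=1)

    # --- expression ------------------------------------------------------
    rq = None
    if config.ct_tsv:
        ct = io.read_tsv(config.ct_tsv)
        calibrator = config.calibrator_week
        if calibrator is None:
            calibrator = int(ct["week"].min())
        rq = ddct(ct, calibrator)
        rq.to_csv(out / "expression_rq.tsv", sep="\t", index=False)
        report["expression"] = {
            "calibrator_week": calibrator,
            "mean_rq_by_week": rq.groupby("week")["rq"].mean().to_dict(),
        }

    # --- TFBS scan -------------------------------------------------------
    motifs = load_motifs(config.motifs_yaml) if config.motifs_yaml else default_motifs()
    hits, per_site = overlap_cpg(scan_motifs(ref, motifs), sites)
    with open(out / "tf_hits.tsv", "w") as fh:
        fh.write("motif\tstart\tend\tstrand\tscore\tcovered_sites\n")
        for h in hits:
            covered = ",".join(map(str, h.covered_sites)) or "."
            fh.write(f"{h.motif}\t{h.start}\t{h.end}\t{h.strand}\t{h.score:.3f}\t{covered}\n")
    covered_sites = sorted(s for s, names in per_site.items() if names)
    report["tfbs"] = {"n_hits": len(hits), "covered_sites": covered_sites}

    # --- association -----------------------------------------------------
    weeks = []
    for g in meth_rows:
        try:
            weeks.append(int(g))
        except ValueError:
            weeks.append(None)
    numeric = all(w is not None for w in weeks) and len(meth_rows) >= 3
    if numeric:
        meth_series = pd.Series(
            {int(g): s.integral_rate for g, s in meth_rows.items()}
        ).sort_index()
        site_rates = pd.DataFrame(
            {int(g): s.per_site_rate for g, s in meth_rows.items()}
        ).T.sort_index()
        corr_rows = []
        if rq is not None:
            expr = rq.groupby("week")["rq"].mean()
            common = meth_series.index.intersection(expr.index)
            res = pearson(meth_series[common], expr[common],
                          labels=("methylation", "expression"))
            corr_rows.append(("overall_methylation_vs_expression", res))
            table = site_correlation_table(
                site_rates, expr, adjust=config.adjust, alpha=config.alpha
            )
            table.to_csv(out / "site_expression_correlation.tsv", sep="\t")
            keys = flag_key_sites(table, set(covered_sites), config.alpha)
            report["key_sites"] = keys
        if color_weekly is not None:
            common = meth_series.index.intersection(color_weekly.index)
            if len(common) >= 3:
                res = pearson(
                    meth_series[common], color_weekly.loc[common, "mean"],
                    labels=("methylation", "color"),
                )
                corr_rows.append(("overall_methylation_vs_color", res))
        if rq is not None and color_weekly is not None:
            expr = rq.groupby("week")["rq"].mean()
            common = color_weekly.index.intersection(expr.index)
            if len(common) >= 3:
                res = pearson(
                    color_weekly.loc[common, "mean"], expr[common],
                    labels=("color", "expression"),
                )
                corr_rows.append(("color_vs_expression", res))
        if corr_rows:
            with open(out / "correlations.tsv", "w") as fh:
                fh.write("series\tr\tp\tn\tstars\n")
                for name, res in corr_rows:
                    fh.write(
                        f"{name}\t{res.r:.6f}\t{res.p:.6g}\t{res.n}\t"
                        f"{significance_stars(res.p)}\n"
                    )
            report["correlations"] = {
                name: {"r": res.r, "p": res.p, "n": res.n} for name, res in corr_rows
            }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
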