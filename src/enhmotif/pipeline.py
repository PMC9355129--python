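"""End-to-end orchestration: scan, enrich, discover, link, quantify.

``run_pipeline`` drives the full analysis on a synthetic dataset (or
user-supplied files via the CLI subcommands) and assembles a report with
five sections — per-motif enrichment, positional bias, discovered flank
words with library matches, the DE contingency test, and exclusive/dual
gene sets — plus a provenance block sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .cooccur import discover_words, extract_flanks, words_to_known_motifs
from .enrichment import (
    bootstrap_enrichment,
    group_differential_enrichment,
    make_flank_controls,
    positional_bias,
)
from .linkage import build_contingency, chi_squared_test, exclusive_motif_genes
from .pwm import DEFAULT_RELSCORE_THRESHOLD, counts_to_pwm, scan_best_hit
from .synthetic import (
    SyntheticConfig,
    demo_motif_library,
    gen_assay_data,
    gen_de_table,
    gen_enhancer_dataset,
)
from .assays import (
    DecaySeries,
    GelLane,
    QPCRMeasure,
    ddct_fold_change,
    fit_half_life,
    percent_exon_retention,
)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _config_hash(config: SyntheticConfig) -> str:
    payload = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: SyntheticConfig,
    outdir=None,
    B: int = 499,
    threshold: float = DEFAULT_RELSCORE_THRESHOLD,
    statistic: str = "count",
) -> dict:
    """Run the full synthetic analysis and return the report dictionary.

    Stages, in order: simulate enhancers and tables; scan the motif library
    and test enhancer-versus-flank enrichment per group; test between-group
    enrichment of the co-motif; check positional bias of the anchor;
    discover words in anchor flanks (Q versus A contrast) and map them to
    the library; build and test the DE contingency table; compute the
    exclusive/dual gene sets; evaluate the assay tables.
    """
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
            "B": B,
            "threshold": threshold,
            "statistic": statistic,
        }
    }
    log.info("stage 1/5: simulating inputs (seed=%d)", config.seed)
    dataset = gen_enhancer_dataset(config)
    groups = dataset.by_group()
    library = demo_motif_library()
    anchor_word = config.spike["Q"][0]
    anchor_id = next(
        (m.motif_id for m in library if m.consensus() == anchor_word),
        library[0].motif_id,
    )
    comotif_id = next(
        (m.motif_id for m in library if m.consensus() == config.comotif_word),
        None,
    )

    log.info("stage 2/5: enrichment of %d motifs in %d enhancers",
             len(library), len(dataset.enhancers))
    enrich_rows = []
    bias_rows = []
    for pcm in library:
        pwm = counts_to_pwm(pcm)
        for group, seqs in sorted(groups.items()):
            seqs = sorted(seqs, key=lambda s: s.name)
            controls = make_flank_controls(seqs, dataset.contigs)
            res = bootstrap_enrichment(
                pwm, seqs, controls, threshold=threshold, B=B,
                seed=config.seed, group=group, statistic=statistic,
            )
            enrich_rows.append(dataclasses.asdict(res))
            if pcm.motif_id == anchor_id:
                hits = [
                    h
                    for h in (scan_best_hit(pwm, s) for s in seqs)
                    if h is not None and h.relative_score >= threshold
                ]
                if hits:
                    bias = positional_bias(
                        hits,
                        {s.name: len(s.seq) for s in seqs},
                        motif_width=pwm.width,
                        group=group,
                    )
                    bias_rows.append(dataclasses.asdict(bias))
        if pcm.motif_id == comotif_id:
            pair = group_differential_enrichment(
                counts_to_pwm(pcm),
                {g: sorted(groups[g], key=lambda s: s.name) for g in groups},
                threshold=threshold, B=B, seed=config.seed,
                statistic=statistic,
            )
            report["group_differential"] = {
                f"{g1}>{g2}": dataclasses.asdict(r)
                for (g1, g2), r in sorted(pair.items())
            }
    # Bonferroni column across all motif x group comparisons, for convenience;
    # raw per-motif p-values remain the primary output
    n_tests = len(enrich_rows)
    for row in enrich_rows:
        row["p_bonferroni"] = min(1.0, row["bootstrap_p"] * n_tests)
    report["enrichment"] = enrich_rows
    report["positional_bias"] = bias_rows

    log.info("stage 3/5: flank word discovery around %s", anchor_word)
    pos = extract_flanks(groups.get("Q", []), anchor_word,
                         config.comotif_half_width, source_group="Q")
    neg = extract_flanks(groups.get("A", []), anchor_word,
                         config.comotif_half_width, source_group="A")
    words = discover_words(pos, neg if len(neg) else None, seed=config.seed)
    matches = words_to_known_motifs(words, library)
    report["discovered_words"] = [
        {
            **dataclasses.asdict(wm),
            "best_match": dataclasses.asdict(match),
        }
        for wm, match in matches
    ]
    if not matches and words:
        report["discovered_words"] = [dataclasses.asdict(w) for w in words]

    log.info("stage 4/5: expression linkage (%d genes)", config.n_genes)
    genes, presence, profiles, de_truth = gen_de_table(config)
    table = build_contingency(genes, presence)
    chi2, df, p = chi_squared_test(table)
    report["contingency"] = {
        "counts": table.counts.astype(int).tolist(),
        "expected": table.expected().tolist(),
        "chi2": chi2,
        "df": df,
        "p": p,
    }
    exclusive = exclusive_motif_genes(profiles)
    dual = exclusive_motif_genes(profiles, require_dual=True)
    report["gene_sets"] = {
        "exclusive_q": sorted(exclusive),
        "exclusive_q_dual": sorted(dual),
        "truth_exclusive_q": de_truth["exclusive_q_genes"],
        "truth_exclusive_q_dual": de_truth["exclusive_q_dual_genes"],
    }

    log.info("stage 5/5: assay quantification")
    assay = gen_assay_data(config)
    psi = [
        percent_exon_retention(
            GelLane(r.sample_id, r.intensity_fl, r.intensity_de6)
        )
        for r in assay["gel"].itertuples()
    ]
    folds = [
        ddct_fold_change(
            QPCRMeasure(r.sample_id, r.ct_target, r.ct_reference,
                        r.ct_target_cal, r.ct_reference_cal)
        )
        for r in assay["qpcr"].itertuples()
    ]
    fits = []
    for sample_id, sub in assay["decay"].groupby("sample_id"):
        series = DecaySeries(
            sample_id, tuple(sub["time_h"]), tuple(sub["intensity"])
        )
        fits.append(fit_half_life(series))
    report["assays"] = {
        "psi_percent_mean": float(sum(psi) / len(psi)),
        "fold_change_mean": float(sum(folds) / len(folds)),
        "t_half_h_mean": float(
            sum(f.t_half for f in fits if f.valid)
            / max(sum(f.valid for f in fits), 1)
        ),
        "truth": assay["truth"],
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dataset.write(outdir)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        log.info("report written to %s", outdir / "report.json")
    return report
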