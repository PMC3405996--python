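"""End-to-end orchestration of the synthetic S-locus analysis workflow.

``run_pipeline`` drives the stages in dependency order on a seeded
synthetic bundle: simulate sequences/panel/F2 → distance matrices →
haplogroup classification and origin assignment → neighbor-joining tree →
segregation model comparison → marker/cluster association → divergence
dating. Every run writes a machine-readable provenance record and, with
the same configuration and seed, byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment import write_fasta
from .association import build_contingency, cramers_v, marker_frequencies
from .divtime import divergence_time, koch_rate, locus_mean_K
from .haplogroups import classify_haplogroup
from .inheritance import compare_models, preset_models
from .io import write_counts_tsv, write_panel_tsv
from .phylogeny import build_matrix, neighbor_joining, write_matrix_tsv, write_newick
from .seqdiv import corrected_distance
from .simulate import (SimulationConfig, haplogroup_of, simulate_f2,
                       simulate_haplogroup_sequences, simulate_panel)


def segregation_report(observed, models=None) -> pd.DataFrame:
    """Model-comparison table: one row per model, ranked best-first."""
    results = compare_models(observed, models)
    rows = []
    for rank, res in enumerate(results, start=1):
        row = {"rank": rank, "model": res.model,
               "chi2": res.chi2, "df": res.df, "p_value": res.p_value,
               "rejected_impossible": res.rejected_impossible}
        for label, e, p in zip(("both", "first_only", "second_only", "neither"),
                               res.expected, res.probabilities):
            row[f"expected_{label}"] = e
            row[f"fraction_{label}"] = f"{p.numerator}/{p.denominator}"
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(outdir, config: SimulationConfig | None = None) -> dict:
    """Run the full synthetic workflow into ``outdir``; returns a summary.

    Outputs: ``sequences.fasta``, ``distances.tsv``, ``tree.nwk``,
    ``haplogroup_calls.tsv``, ``panel.tsv``, ``f2_counts.tsv``,
    ``segregation.tsv``, ``association.json``, ``frequencies.tsv``,
    ``divtime.json`` and ``provenance.json``.
    """
    cfg = config or SimulationConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- sequences, distances, tree -------------------------------------
    aln = simulate_haplogroup_sequences(cfg)
    write_fasta(aln, out / "sequences.fasta")
    dm = build_matrix(aln, method="K2P")
    write_matrix_tsv(dm, out / "distances.tsv")
    tree = neighbor_joining(dm)
    (out / "tree.nwk").write_text(write_newick(tree) + "\n")

    # --- haplogroup classification (leave-one-out against the panel) ----
    calls = []
    for label in aln.labels:
        refs = aln.subset([l for l in aln.labels if l != label])
        call = classify_haplogroup(aln.sequence(label), refs,
                                   query_label=label)
        calls.append({
            "query": label, "best_reference": call.best_reference,
            "identity": round(call.identity), "call": call.call,
            "true_haplogroup": haplogroup_of(label),
            "hit_same_group": haplogroup_of(call.best_reference)
            == haplogroup_of(label),
        })
    pd.DataFrame(calls).to_csv(out / "haplogroup_calls.tsv", sep="\t",
                               index=False)

    # --- segregation ------------------------------------------------------
    models = preset_models()
    f2_counts = simulate_f2(models[cfg.f2_model], cfg.f2_n, seed=cfg.seed + 2)
    write_counts_tsv(f2_counts, out / "f2_counts.tsv")
    observed = list(f2_counts.values())
    seg = segregation_report(observed)
    seg.to_csv(out / "segregation.tsv", sep="\t", index=False)

    # --- panel, association, frequencies ---------------------------------
    panel = simulate_panel(cfg)
    write_panel_tsv(panel, out / "panel.tsv")
    sub_of = cfg.subgenome_of()
    sub1_markers = [m for m, s in sub_of.items() if s == "sub1"]
    table = build_contingency(panel, sub1_markers)
    assoc = cramers_v(table)
    assoc_report = {
        "markers": sub1_markers,
        "cramers_v": assoc.V,
        "chi2": assoc.chi2,
        "fisher_two_tailed_p": assoc.p_value,
        "excluded_accessions": table.excluded,
        "table": assoc.table.to_frame().to_dict(),
    }
    (out / "association.json").write_text(json.dumps(assoc_report, indent=2))
    freqs = marker_frequencies(panel, sub_of)
    freqs.to_csv(out / "frequencies.tsv", sep="\t", index=False)

    # --- divergence dating: subgenome-1 vs subgenome-2 consensus ---------
    h1 = aln.sequence("H1_s1")
    h2 = aln.sequence("H2_s1")
    est = corrected_distance(h1, h2, "JC")
    mean_k, se_k, ci_k = locus_mean_K([est])
    te = divergence_time(mean_k, ci_k, koch_rate())
    dt_report = {
        "K": mean_k, "K_se": se_k, "K_ci": list(ci_k),
        "rate_model": te.rate_model,
        "T_years": te.T, "T_ci_years": list(te.T_ci),
    }
    (out / "divtime.json").write_text(json.dumps(dt_report, indent=2))

    provenance = {
        "package": "polysloc",
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "outputs": sorted(p.name for p in out.iterdir()
                          if p.name != "provenance.json"),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return {
        "n_sequences": aln.n_sequences,
        "classification_accuracy": float(pd.DataFrame(calls)["hit_same_group"].mean()),
        "best_model": seg.iloc[0]["model"],
        "cramers_v": assoc.V,
        "f2_counts": f2_counts,
        "T_years": te.T,
        "outdir": str(out),
    }
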