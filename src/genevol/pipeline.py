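"""Seeded end-to-end demo: generate every synthetic fixture, run every
stage, and compare the estimates with the recorded truth.

The demo is the pipeline's self-test on data with known ground truth; its
report states, per stage, the estimate, the truth, and whether the estimate
falls within the stage's stated tolerance.  All randomness derives from the
single config seed, so a rerun with the same seed writes identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import (
    centromere_scan,
    codon_evolution,
    gene_family_screen,
    io_formats,
    ltr_dating,
    synthetic_data,
)
from .config import RunConfig
from .expression_summary import ExpressionMatrix, stage_fold_change

__all__ = ["run_demo"]

# Demo problem sizes: large enough for the stochastic tolerances below,
# small enough to run in seconds.
_N_CODON_PAIRS = 400
_N_CODONS = 300
_CODON_TV_TARGET = 0.5
_N_LTR = 200
_LTR_AGE_MYA = 1.5
_LTR_LENGTH = 1000
_SAT_CHROM_LEN = 2_000_000
_SAT_COPIES = 300
_SAT_LOCUS = 900_000
_SAT_MONOMER_LEN = 161


def run_demo(cfg: RunConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc
    (outdir / "config.json").write_text(json.dumps(asdict(cfg), indent=2, sort_keys=True) + "\n")
    checks: dict[str, dict] = {}

    # --- 4DTv recovery -----------------------------------------------------
    hky = synthetic_data.HKYParams(kappa=2.0)
    distance = synthetic_data.distance_for_transversion_distance(_CODON_TV_TARGET, hky)
    pairs, truth = synthetic_data.simulate_codon_pair_set(
        _N_CODON_PAIRS, _N_CODONS, distance, hky, seed=cfg.seed
    )
    summary = codon_evolution.paranome_4dtv(pairs, cfg.min_4d_sites, cfg.bin_4dtv)
    expected = truth.items["expected_corrected_4dtv"]
    checks["codon_peak"] = {
        "estimate": summary.peak,
        "truth": expected,
        # modal-bin midpoint within one bin of the truth-containing bins
        # (the truth may sit exactly on a bin edge)
        "pass": bool(abs(summary.peak - expected) <= 1.5 * cfg.bin_4dtv + 1e-9),
    }

    # --- LTR age recovery --------------------------------------------------
    records, ltr_truth = synthetic_data.simulate_ltr_cohort(
        _N_LTR, _LTR_AGE_MYA, cfg.rate, _LTR_LENGTH, seed=cfg.seed + 1
    )
    io_formats.write_fasta(records, outdir / "ltr_pairs.fa")
    cohort = [
        ltr_dating.date_pair(a.id.rsplit("_", 1)[0], a.seq, b.seq, cfg.rate)
        for a, b in zip(records[::2], records[1::2])
    ]
    ages = np.array([p.T_mya for p in cohort if p.T_mya is not None])
    se = ages.std(ddof=1) / np.sqrt(len(ages))
    checks["ltr_mean_age"] = {
        "estimate": float(ages.mean()),
        "truth": _LTR_AGE_MYA,
        "pass": bool(abs(ages.mean() - _LTR_AGE_MYA) <= 3 * se),
    }

    # --- satellite recovery ------------------------------------------------
    rng = np.random.default_rng(cfg.seed + 2)
    monomer = "".join("ACGT"[i] for i in rng.integers(4, size=_SAT_MONOMER_LEN))
    chrom, dat, sat_truth = synthetic_data.plant_satellite_chromosome(
        _SAT_CHROM_LEN, monomer, _SAT_COPIES, _SAT_LOCUS, 0.05, seed=cfg.seed + 2
    )
    io_formats.write_trf_dat(dat, outdir / "repeats.dat")
    clusters = centromere_scan.cluster_monomers(
        io_formats.read_trf_dat(outdir / "repeats.dat"),
        cfg.min_monomer_identity,
        (cfg.period_min, cfg.period_max),
    )
    base = centromere_scan.base_repeat(clusters)
    hits = centromere_scan.map_monomer([chrom], base.representative_monomer)
    calls = centromere_scan.call_centromeres(
        hits, {chrom.id: len(chrom.seq)}, cfg.window, cfg.min_fraction, base
    )
    call = calls[0]
    locus = sat_truth.items["locus"]
    locus_ok = (
        call.status == "called"
        and call.start0 <= locus[0] + cfg.window
        and call.end0 >= locus[1] - cfg.window
    )
    checks["satellite"] = {
        "estimate": {
            "monomer_length": len(base.representative_monomer),
            "call": [call.start0, call.end0],
        },
        "truth": {"monomer_length": _SAT_MONOMER_LEN, "locus": locus},
        "pass": bool(locus_ok and len(base.representative_monomer) == _SAT_MONOMER_LEN),
    }

    # --- gene-family screen ------------------------------------------------
    genes, fam_hits, domains, fam_truth = synthetic_data.make_family_fixture(
        50, 12, ("chr4", 10, 270_000), seed=cfg.seed + 3
    )
    members = gene_family_screen.screen_family(
        fam_hits, domains, set(fam_truth.params["query_domains"]),
        cfg.max_evalue, cfg.min_identity, cfg.min_coverage,
    )
    member_models = [g for g in genes if g.gene_id in members]
    arrays = gene_family_screen.detect_tandem_arrays(
        member_models, genes, cfg.max_gap_bp, cfg.max_intervening
    )
    cluster_arrays = [a for a in arrays if a.chrom == "chr4"]
    checks["family_screen"] = {
        "estimate": sorted(members),
        "truth": sorted(fam_truth.items["members"]),
        "pass": bool(members == set(fam_truth.items["members"])),
    }
    checks["tandem_array"] = {
        "estimate": [[a.n_genes, a.span_bp] for a in cluster_arrays],
        "truth": [[10, 270_000]],
        "pass": len(cluster_arrays) == 1
        and cluster_arrays[0].n_genes == 10
        and cluster_arrays[0].span_bp == 270_000,
    }

    # --- expression fold-change recovery -----------------------------------
    counts, lengths, expr_truth = synthetic_data.make_expression_fixture(
        200, ["85DAF", "100DAF"], ([0, 1, 2], 4.7, ("85DAF", "100DAF")),
        seed=cfg.seed + 4,
    )
    matrix = ExpressionMatrix(counts, lengths)
    fold = stage_fold_change(matrix, "85DAF", "100DAF", cfg.pseudocount)
    top = set(fold.index[:3])
    checks["expression_fold"] = {
        "estimate": sorted(top),
        "truth": sorted(expr_truth.items["upregulated"]),
        "pass": bool(top == set(expr_truth.items["upregulated"])),
    }

    report = {"seed": cfg.seed, "checks": checks}
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
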