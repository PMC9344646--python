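"""End-to-end pipeline: simulate -> balance -> TADs -> compartments -> inter-TAD.

The pipeline mirrors the downstream Hi-C analysis it packages: KR-balanced
25 kb maps, insulation-score boundaries (500 kb window) with a 3-bin overlap
tolerance between conditions, 100 kb compartment eigenvectors oriented by GC,
and the inter-TAD fold-change / lamina-association comparison with its
boundary-permutation control.  Run on synthetic maps it also scores every
stage against the planted truth.

All constants live in one flat configuration dictionary (see
:data:`DEFAULT_CONFIG`); every CLI flag mirrors a config key.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .contact_io import ContactMatrix, balance_kr, coarsen
from .tad_calling import (
    TadSegmentation,
    call_boundaries,
    insulation_score,
    match_boundaries,
)
from .compartments import (
    call_compartment_changes,
    compare_compartments,
    compartment_eigenvector,
)
from .intertad_lad import (
    _finite_mean,
    build_pair_table,
    classify_lad_pairs,
    compare_size_distributions,
    permute_boundaries_control,
    select_extreme_pairs,
)
from .synthetic_data import (
    GenomeSpec,
    SyntheticTruth,
    decoupled_track,
    evaluate_boundaries,
    generate_truth,
    planted_compartment_at,
    render_contact_map,
    write_fixture_bundle,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "load_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    # synthetic genome
    "chrom_lengths": {"chr1": 10_000_000},
    "resolution": 25_000,
    "depth": None,  # expected contacts per chromosome; None = 5e5 per Mb
    "tad_size_median": 800_000,
    "tad_size_sigma": 0.35,
    "alpha": -1.0,
    "beta": 3.0,
    "gamma": 1.6,
    "delta_log2": 1.25,
    "weakened_fraction": 0.24,
    "strengthened_fraction": 0.18,
    "mixed_weakened_prop": 0.75,
    "lad_prob_b": 0.70,
    "lad_prob_a": 0.25,
    # balancing
    "balance_tol": 1e-5,
    "balance_max_iter": 1000,
    "balance_min_nnz": 10,
    # TAD calling
    "insulation_window": 500_000,
    "strength_min": 0.1,
    "tol_bins": 3,
    # compartments
    "compartment_resolution": 100_000,
    # inter-TAD analysis
    "min_tad_bp": 500_000,
    "logfc_cut": 1.0,
    "selection_mode": "threshold",
    "k_per_distance": 2,
    "lad_threshold": 0.0,
    "n_permutations": 100,
    # reproducibility
    "seed": 7,
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Merge a YAML key-value file over the defaults."""
    config = {**DEFAULT_CONFIG}
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        config.update(user)
    return config


def _genome_spec(config: dict[str, Any]) -> GenomeSpec:
    return GenomeSpec(
        chrom_lengths=dict(config["chrom_lengths"]),
        resolution=config["resolution"],
        depth=config["depth"],
        tad_size_median=config["tad_size_median"],
        tad_size_sigma=config["tad_size_sigma"],
        alpha=config["alpha"],
        beta=config["beta"],
        gamma=config["gamma"],
        delta_log2=config["delta_log2"],
        weakened_fraction=config["weakened_fraction"],
        strengthened_fraction=config["strengthened_fraction"],
        mixed_weakened_prop=config["mixed_weakened_prop"],
        lad_prob_b=config["lad_prob_b"],
        lad_prob_a=config["lad_prob_a"],
        min_tad_bp=config["min_tad_bp"],
        seed=config["seed"],
    )


def _match_tads(called: TadSegmentation, planted: np.ndarray) -> np.ndarray:
    """Map each called TAD to the planted TAD with maximal bin overlap (-1 if none)."""
    out = np.full(len(called.tads), -1, dtype=np.int64)
    for k, (s, e) in enumerate(called.tads):
        best, best_ov = -1, 0
        for j, (ps, pe) in enumerate(planted):
            ov = min(e, pe) - max(s, ps)
            if ov > best_ov:
                best, best_ov = j, ov
        out[k] = best
    return out


def run_pipeline(
    config: dict[str, Any], outdir: str | Path | None = None
) -> dict[str, Any]:
    """Execute every stage on a simulated WT/KO pair and return the summary.

    When ``outdir`` is given, fixture files, per-stage tables and the summary
    plus a run manifest (config snapshot, seed, versions, output hashes) are
    written there.
    """
    spec = _genome_spec(config)
    seed = int(config["seed"])
    truth = generate_truth(spec)

    maps = {
        "wt": render_contact_map(truth, "wt", noise_seed=seed + 1),
        "ko": render_contact_map(truth, "ko", noise_seed=seed + 2),
        "wt_rep": render_contact_map(truth, "wt", noise_seed=seed + 3),
    }

    balanced: dict[str, dict[str, ContactMatrix]] = {}
    for cond, per_chrom in maps.items():
        balanced[cond] = {
            chrom: balance_kr(
                m,
                tol=config["balance_tol"],
                max_iter=config["balance_max_iter"],
                min_nnz=config["balance_min_nnz"],
            )
            for chrom, m in per_chrom.items()
        }

    # --- TAD boundaries -----------------------------------------------------
    segs: dict[str, dict[str, TadSegmentation]] = {}
    for cond in ("wt", "ko", "wt_rep"):
        segs[cond] = {}
        for chrom, m in balanced[cond].items():
            prof = insulation_score(m, window=config["insulation_window"])
            segs[cond][chrom] = call_boundaries(
                prof, strength_min=config["strength_min"]
            )

    def pooled_overlap(a: str, b: str) -> dict[str, float]:
        na = nb = nm = 0
        for chrom in spec.chrom_lengths:
            rep = match_boundaries(
                segs[a][chrom], segs[b][chrom], tol_bins=config["tol_bins"]
            )
            na += len(segs[a][chrom].boundaries)
            nb += len(segs[b][chrom].boundaries)
            nm += len(rep.matches)
        fa = nm / na if na else 0.0
        fb = nm / nb if nb else 0.0
        return {"fraction_a": fa, "fraction_b": fb, "mean": 0.5 * (fa + fb)}

    recalls, precisions = [], []
    n_planted = n_called = 0
    for chrom in spec.chrom_lengths:
        r, p = evaluate_boundaries(segs["wt"][chrom], truth.boundaries[chrom])
        recalls.append(r)
        precisions.append(p)
        n_planted += len(truth.boundaries[chrom])
        n_called += len(segs["wt"][chrom].boundaries)
    boundary_summary = {
        "n_planted": n_planted,
        "n_called_wt": n_called,
        "recall": float(np.mean(recalls)),
        "precision": float(np.mean(precisions)),
        "overlap_wt_ko": pooled_overlap("wt", "ko"),
        "overlap_wt_rep": pooled_overlap("wt", "wt_rep"),
    }

    # --- compartments -------------------------------------------------------
    comp_factor = config["compartment_resolution"] // spec.resolution
    profiles: dict[str, list] = {"wt": [], "ko": []}
    r_vs_planted: dict[str, float] = {}
    for cond in ("wt", "ko"):
        for chrom, m in maps[cond].items():
            coarse = balance_kr(
                coarsen(m, comp_factor),
                tol=config["balance_tol"],
                max_iter=config["balance_max_iter"],
                min_nnz=config["balance_min_nnz"],
            )
            prof = compartment_eigenvector(coarse, truth.gc)
            profiles[cond].append(prof)
            if cond == "wt":
                planted = planted_compartment_at(
                    truth, chrom, config["compartment_resolution"]
                )
                both = prof.valid & np.isfinite(planted[: len(prof.eigenvector)])
                if both.sum() >= 3:
                    r_vs_planted[chrom] = float(
                        np.corrcoef(prof.eigenvector[both], planted[: len(both)][both])[
                            0, 1
                        ]
                    )
    per_chrom_r, genome_r = compare_compartments(profiles["wt"], profiles["ko"])
    changes = [
        call_compartment_changes(a, b)
        for a, b in zip(profiles["wt"], profiles["ko"])
    ]
    compartment_summary = {
        "per_chrom_r_wt_ko": per_chrom_r,
        "genome_wide_r_wt_ko": genome_r,
        "r_vs_planted": r_vs_planted,
        "mean_abs_r_vs_planted": float(
            np.mean([abs(v) for v in r_vs_planted.values()])
        )
        if r_vs_planted
        else float("nan"),
        "n_change_regions": int(sum(len(c) for c in changes)),
    }

    # --- inter-TAD fold change and lamina association -----------------------
    table = build_pair_table(
        balanced["wt"],
        balanced["ko"],
        segs["wt"],
        damid=truth.damid,
        min_tad_bp=config["min_tad_bp"],
        lad_threshold=config["lad_threshold"],
    )
    decreased, increased = select_extreme_pairs(
        table,
        mode=config["selection_mode"],
        k=config["k_per_distance"],
        logfc_cut=config["logfc_cut"],
    )
    lad_report = classify_lad_pairs(
        decreased, increased, lad_threshold=config["lad_threshold"]
    )

    logfc_r = _planted_logfc_correlation(table, segs["wt"], truth)

    ks_d = ks_p = float("nan")
    if len(decreased) and len(increased):
        sizes_dec = np.concatenate(
            [
                (decreased["tad1_end"] - decreased["tad1_start"]).to_numpy(),
                (decreased["tad2_end"] - decreased["tad2_start"]).to_numpy(),
            ]
        )
        sizes_inc = np.concatenate(
            [
                (increased["tad1_end"] - increased["tad1_start"]).to_numpy(),
                (increased["tad2_end"] - increased["tad2_start"]).to_numpy(),
            ]
        )
        ks_d, ks_p = compare_size_distributions(sizes_dec, sizes_inc)

    control = permute_boundaries_control(
        segs["wt"],
        balanced["wt"],
        balanced["ko"],
        truth.damid,
        n_permutations=config["n_permutations"],
        seed=seed + 10,
        mode=config["selection_mode"],
        k=config["k_per_distance"],
        logfc_cut=config["logfc_cut"],
        min_tad_bp=config["min_tad_bp"],
        lad_threshold=config["lad_threshold"],
    )
    # null calibration: same protocol with a lamina track decoupled from the
    # contact structure — the control must show no dec/inc separation there
    null_control = permute_boundaries_control(
        segs["wt"],
        balanced["wt"],
        balanced["ko"],
        decoupled_track(truth.damid, seed=seed + 20),
        n_permutations=config["n_permutations"],
        seed=seed + 10,
        mode=config["selection_mode"],
        k=config["k_per_distance"],
        logfc_cut=config["logfc_cut"],
        min_tad_bp=config["min_tad_bp"],
        lad_threshold=config["lad_threshold"],
    )
    observed_sep = lad_report.mixed_pct("decreased") - lad_report.mixed_pct(
        "increased"
    )
    intertad_summary = {
        "n_pairs": len(table),
        "n_excluded_zero": table.n_excluded_zero,
        "n_excluded_masked": table.n_excluded_masked,
        "median_logfc": float(table.df["logfc"].median()) if len(table) else 0.0,
        "selection_mode": config["selection_mode"],
        "n_decreased": int(len(decreased)),
        "n_increased": int(len(increased)),
        "lad_counts": lad_report.counts,
        "lad_percentages": lad_report.percentages,
        "logfc_vs_planted_r": logfc_r,
        "ks": {"d": ks_d, "p": ks_p},
        "permutation": {
            "n": control.n_permutations,
            "mean_mixed_decreased": _finite_mean(control.mixed_pct_decreased),
            "mean_mixed_increased": _finite_mean(control.mixed_pct_increased),
            "separation": control.separation,
            "separation_sd": control.separation_sd,
            "observed_separation": float(observed_sep),
        },
        "permutation_null_damid": {
            "n": null_control.n_permutations,
            "mean_mixed_decreased": _finite_mean(null_control.mixed_pct_decreased),
            "mean_mixed_increased": _finite_mean(null_control.mixed_pct_increased),
            "separation": null_control.separation,
            "separation_sd": null_control.separation_sd,
        },
    }

    summary = {
        "seed": seed,
        "boundaries": boundary_summary,
        "compartments": compartment_summary,
        "intertad": intertad_summary,
    }

    if outdir is not None:
        _write_outputs(outdir, config, summary, truth, maps, table)
    return summary


def _planted_logfc_correlation(
    table, segs: dict[str, TadSegmentation], truth: SyntheticTruth
) -> float:
    """Pearson r between planted log2 factors and recovered LogFC (perturbed pairs).

    Called TADs are matched to planted TADs by maximal overlap; a pair is
    perturbed when its matched planted pair carries a factor != 1.
    """
    planted_vals, recovered_vals = [], []
    for chrom, seg in segs.items():
        planted_logfc = truth.planted_logfc(chrom)
        if not planted_logfc:
            continue
        mapping = _match_tads(seg, truth.tads[chrom])
        tads = seg.tads
        res = seg.resolution
        coord_to_called = {
            (int(s) * res, int(e) * res): k for k, (s, e) in enumerate(tads)
        }
        sub = table.df[table.df["chrom"] == chrom]
        for row in sub.itertuples():
            k1 = coord_to_called.get((row.tad1_start, row.tad1_end))
            k2 = coord_to_called.get((row.tad2_start, row.tad2_end))
            if k1 is None or k2 is None:
                continue
            p1, p2 = mapping[k1], mapping[k2]
            if p1 < 0 or p2 < 0 or p1 == p2:
                continue
            key = (min(p1, p2), max(p1, p2))
            if key in planted_logfc:
                planted_vals.append(planted_logfc[key])
                recovered_vals.append(row.logfc)
    if len(planted_vals) < 3 or np.std(planted_vals) == 0:
        return float("nan")
    return float(np.corrcoef(planted_vals, recovered_vals)[0, 1])


def _write_outputs(outdir, config, summary, truth, maps, table) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture_paths = write_fixture_bundle(
        truth, {c: maps[c] for c in ("wt", "ko")}, outdir / "fixtures"
    )
    table_path = outdir / "pair_table.tsv"
    table.df.to_csv(table_path, sep="\t", index=False)
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    outputs = {str(p): _sha256(p) for p in [*fixture_paths.values(), table_path, summary_path]}
    manifest = {
        "config": {k: (dict(v) if isinstance(v, dict) else v) for k, v in config.items()},
        "seed": config["seed"],
        "versions": {
            "tadlamina": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
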