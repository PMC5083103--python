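"""Simulation studies that measure the pipeline's operating characteristics.

Each routine generates synthetic studies under the default study
conditions, runs the relevant pipeline stages from scratch, and reports an
aggregate: null calibration and power of the differential model,
column-dendrogram recovery of the correlated TLR-agonist structure, and
cross-omics concordance recovery and null behavior. They are used by the
test suite and the acceptance script; sizes are arguments so callers can
scale replication counts.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import concordance as _cc
from . import filters as _filters
from . import quantify as _q
from .cluster import two_way_cluster
from .differential import fit_paired_count_model
from .io import validate_design
from .simulate import SimulationConfig, simulate_spc_experiment, simulate_transcriptome

__all__ = [
    "differential_null_calibration",
    "differential_power",
    "tlr_coclustering_fraction",
    "concordance_recovery",
    "concordance_null_fraction",
]

CONTRAST = ("adult", "MPLA")


def _fit(study, contrast=CONTRAST, alpha=0.05):
    design = validate_design(study.spc, study.samples)
    return fit_paired_count_model(study.spc, design, contrast, alpha=alpha)


def differential_null_calibration(
    n_datasets: int = 200, n_proteins: int = 500, n_subjects: int = 6, seed: int = 1000
) -> dict:
    """Raw p<0.05 fraction and BH-5% false-discovery proportion under the
    global null (no responsive proteins)."""
    raw, fdp = [], []
    for k in range(n_datasets):
        study = simulate_spc_experiment(
            SimulationConfig(
                n_proteins=n_proteins,
                n_subjects_per_age=n_subjects,
                frac_responsive=0.0,
                seed=seed + k,
            )
        )
        res = _fit(study)
        raw.append(float((res["p"] < 0.05).mean()))
        n_called = int(res["significant"].sum())
        fdp.append(1.0 if n_called > 0 else 0.0)  # every call is false under the null
    return {
        "raw_p_fraction": float(np.mean(raw)),
        "empirical_fdr": float(np.mean(fdp)),
        "n_datasets": n_datasets,
    }


def differential_power(
    n_datasets: int = 200, n_proteins: int = 500, n_subjects: int = 6, seed: int = 2000
) -> dict:
    """Sensitivity and false-discovery proportion on mixed simulations
    (default 20% responsive at 2 log2 units, 6 pairs)."""
    sens, fdp = [], []
    for k in range(n_datasets):
        study = simulate_spc_experiment(
            SimulationConfig(
                n_proteins=n_proteins, n_subjects_per_age=n_subjects, seed=seed + k
            )
        )
        res = _fit(study)
        truth = study.truth.query("treatment == @CONTRAST[1]").set_index("protein")
        resp = truth["responsive"].reindex(res.index).to_numpy()
        called = res["significant"].to_numpy()
        sens.append(float(called[resp].mean()))
        fdp.append(float((called & ~resp).sum() / max(called.sum(), 1)))
    return {
        "sensitivity": float(np.mean(sens)),
        "empirical_fdr": float(np.mean(fdp)),
        "n_datasets": n_datasets,
    }


def tlr_coclustering_fraction(n_seeds: int = 100, n_proteins: int = 500, seed: int = 4000) -> dict:
    """Fraction of seeds whose adult column dendrogram merges the two
    correlated TLR-agonist conditions (MPLA, R848) before Alum."""
    hits = 0
    for k in range(n_seeds):
        study = simulate_spc_experiment(
            SimulationConfig(n_proteins=n_proteins, seed=seed + k)
        )
        design = validate_design(study.spc, study.samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm = _q.normalize_total_spc(_q.impute_half_min(study.spc))
            fc = _q.fold_change(norm, design)
            included = _filters.cluster_inclusion_filter(fc, study.spc, study.samples)
        mat = fc.mean_log2.loc[included.any(axis=1)]["adult"]
        mat = mat.loc[mat.std(axis=1, ddof=1) > 0]
        z = _q.zscore_rows(mat)
        _, col_dend, _ = two_way_cluster(z)
        first = col_dend.merge_pairs()[0]
        merged = {col_dend.labels[i] for i in first}
        hits += merged == {"MPLA", "R848"}
    return {"fraction": hits / n_seeds, "n_seeds": n_seeds}


def _concordance_once(seed: int, frac_concordant: float, n_background_genes: int = 2500):
    cfg = SimulationConfig(seed=seed)
    study = simulate_spc_experiment(cfg)
    design = validate_design(study.spc, study.samples)
    prot = fit_paired_count_model(study.spc, design, CONTRAST)
    expr, ann, probe_map, gene_map, _truth = simulate_transcriptome(
        cfg,
        frac_concordant=frac_concordant,
        treatment=CONTRAST[1],
        n_background_genes=n_background_genes,
    )
    calls = _cc.call_gene_changes(_cc.quantile_normalize(expr), ann, "T1", "T2", probe_map)
    matched = _cc.match_molecules(calls, prot, gene_map, keep_unmatched_genes=True)
    return _cc.concordance_test(matched, background_n=len(matched))


def concordance_recovery(
    fracs=(0.0, 0.5, 1.0), n_seeds: int = 10, seed: int = 5000
) -> dict:
    """Mean concordant-molecule count at several true concordant fractions."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for frac in fracs:
            counts = [
                _concordance_once(seed + k, frac).n_concordant for k in range(n_seeds)
            ]
            out[frac] = float(np.mean(counts))
    return {"mean_concordant": out, "n_seeds": n_seeds}


def concordance_null_fraction(n_seeds: int = 200, seed: int = 6000) -> dict:
    """Fraction of null (frac_concordant=0) seeds with tau-b p < 0.05."""
    ps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_seeds):
            ps.append(_concordance_once(seed + k, 0.0).p)
    ps = np.asarray(ps)
    return {"p_below_05_fraction": float((ps < 0.05).mean()), "n_seeds": n_seeds}
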