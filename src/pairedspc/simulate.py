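"""Synthetic paired secretome and transcriptome studies with known truth.

The generator emulates the statistical structure of a paired monocyte
stimulation experiment (newborn and adult subjects, each contributing one
control and several adjuvant-treated samples drawn around a shared
subject baseline) and of a paired multi-timepoint expression-array study
(participants measured at T1..Tk, a known subset of genes shifting at T2
in the direction of the matching protein effect).

Count model: negative binomial around per-subject log-normal baselines;
``baseline_dispersion -> 0`` recovers Poisson. Responsive proteins shift
by a per-protein true log2 effect under their treatment. Missingness is
missing-not-at-random: low counts are masked as undetected with a
probability that decays with the count, scaled by ``dropout_rate``.

Seeding: one integer seed fans out to named substreams (structure,
counts, dropout, expression, genesets), so adding a downstream stage
never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GeneSetCollection

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_spc_experiment",
    "simulate_transcriptome",
    "simulate_genesets",
    "write_study",
]

_STREAMS = ("structure", "counts", "dropout", "expression", "genesets")


class ConfigurationError(ValueError):
    """Invalid simulation configuration; names the offending field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic paired secretome experiment.

    Defaults mirror the emulated design: 6 paired subjects per age group,
    four treatment conditions with one control, 500 proteins of which 20%
    respond with a mean true effect of 2 log2 units, mild extra-Poisson
    count noise (spectral counting is near-Poisson at the technical level;
    subject-level variability enters through the log-normal baseline), and
    10% missing-not-at-random detection dropout. MPLA- and R848-responsive
    protein sets overlap by 80% with shared effects (a common TLR-driven
    secretion program), while Alum draws an independent set.
    """

    n_subjects_per_age: int = 6
    treatments: tuple[str, ...] = ("control", "Alum", "MPLA", "R848")
    control_label: str = "control"
    n_proteins: int = 500
    frac_responsive: float = 0.2
    effect_log2fc: float = 2.0
    effect_sd: float = 0.25
    baseline_dispersion: float = 0.05
    dropout_rate: float = 0.1
    protein_length_range: tuple[int, int] = (100, 1500)
    subject_sigma: float = 0.3
    abundance_log_median: float = float(np.log(4.0))
    abundance_sigma: float = 1.0
    detection_scale: float = 3.0
    responsive_overlap: dict = field(default_factory=lambda: {("MPLA", "R848"): 0.8})
    unpaired_newborn: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects_per_age < 1:
            raise ConfigurationError("n_subjects_per_age must be a positive count")
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be a positive count")
        if list(self.treatments).count(self.control_label) != 1:
            raise ConfigurationError(
                "treatments must include the control_label exactly once"
            )
        if len(set(self.treatments)) != len(self.treatments):
            raise ConfigurationError("treatments must be unique")
        for name in ("frac_responsive", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("effect_sd", "subject_sigma", "abundance_sigma", "detection_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.baseline_dispersion < 0:
            raise ConfigurationError("baseline_dispersion must be non-negative")
        lo, hi = self.protein_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("protein_length_range must be a valid positive range")
        for pair, frac in self.responsive_overlap.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"responsive_overlap[{pair}] must lie in [0, 1]")

    @property
    def adjuvants(self) -> tuple[str, ...]:
        return tuple(t for t in self.treatments if t != self.control_label)

    def rng(self, stream: str) -> np.random.Generator:
        if stream not in _STREAMS:
            raise ValueError(f"unknown stream {stream!r}")
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS.index(stream)])


@dataclass
class SyntheticStudy:
    """A generated experiment: counts, sample sheet, protein info, truth.

    ``truth`` has one row per (protein, adjuvant) with the responsiveness
    flag and the true log2 effect (0 for non-responsive entries).
    """

    spc: pd.DataFrame
    samples: pd.DataFrame
    proteins: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def responsive(self, treatment: str) -> list[str]:
        t = self.truth
        sel = (t["treatment"] == treatment) & t["responsive"]
        return t.loc[sel, "protein"].tolist()


def _draw_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Responsive sets and true effects per adjuvant, with overlap structure."""
    proteins = [f"P{i:05d}" for i in range(config.n_proteins)]
    k = int(round(config.frac_responsive * config.n_proteins))
    chosen: dict[str, np.ndarray] = {}
    effects: dict[str, np.ndarray] = {}
    shared_effect: dict[str, float] = {}
    for adj in config.adjuvants:
        overlap_src = None
        for (a, b), frac in config.responsive_overlap.items():
            if adj == b and a in chosen:
                overlap_src = (a, frac)
        if overlap_src is None:
            idx = rng.choice(config.n_proteins, size=k, replace=False)
        else:
            src, frac = overlap_src
            n_shared = int(round(frac * k))
            shared = rng.choice(chosen[src], size=min(n_shared, len(chosen[src])), replace=False)
            # extras avoid the source set entirely so the overlap is exact
            pool = np.setdiff1d(np.arange(config.n_proteins), chosen[src])
            extra = rng.choice(pool, size=k - len(shared), replace=False)
            idx = np.concatenate([shared, extra])
        chosen[adj] = np.sort(idx)
        eff = rng.normal(config.effect_log2fc, config.effect_sd, size=k)
        effects[adj] = eff
    rows = []
    for adj in config.adjuvants:
        eff_by_idx = dict(zip(chosen[adj], effects[adj]))
        # shared proteins reuse the first treatment's effect draw -> correlated profiles
        for (a, b), _frac in config.responsive_overlap.items():
            if adj == b and a in chosen:
                src_eff = dict(zip(chosen[a], effects[a]))
                for i in chosen[adj]:
                    if i in src_eff:
                        eff_by_idx[i] = src_eff[i]
        resp = set(chosen[adj].tolist())
        for i, prot in enumerate(proteins):
            rows.append(
                {
                    "protein": prot,
                    "treatment": adj,
                    "responsive": i in resp,
                    "true_log2fc": float(eff_by_idx.get(i, 0.0)),
                }
            )
    return pd.DataFrame(rows)


def simulate_spc_experiment(config: SimulationConfig) -> SyntheticStudy:
    """Generate a paired spectral-count experiment with known ground truth."""
    rng_s = config.rng("structure")
    rng_c = config.rng("counts")
    rng_d = config.rng("dropout")

    # truth is drawn first on the structure stream so the transcriptome
    # generator (which re-derives it from the same config) sees the same
    # responsive sets
    truth = _draw_truth(config, rng_s)
    proteins = [f"P{i:05d}" for i in range(config.n_proteins)]
    lo, hi = config.protein_length_range
    lengths = rng_s.integers(lo, hi + 1, size=config.n_proteins)
    gene_symbols = [f"GENE{i:05d}" for i in range(config.n_proteins)]
    protein_info = pd.DataFrame(
        {"gene_symbol": gene_symbols, "length": lengths},
        index=pd.Index(proteins, name="id"),
    )
    effect = {
        (row.protein, row.treatment): row.true_log2fc
        for row in truth.itertuples(index=False)
        if row.responsive
    }

    subjects = []
    for age, prefix in (("newborn", "N"), ("adult", "A")):
        n = config.n_subjects_per_age + (1 if (config.unpaired_newborn and age == "newborn") else 0)
        subjects += [(age, f"{prefix}{i + 1:02d}") for i in range(n)]

    base_abundance = np.exp(
        rng_c.normal(config.abundance_log_median, config.abundance_sigma, size=config.n_proteins)
    )
    sample_rows = []
    columns = {}
    for age, subject in subjects:
        b_subject = float(np.exp(rng_c.normal(0.0, config.subject_sigma)))
        unpaired = config.unpaired_newborn and subject == f"N{config.n_subjects_per_age + 1:02d}"
        for treatment in config.treatments:
            if unpaired and treatment == config.control_label:
                continue  # the extra newborn lacks a control sample
            sample_id = f"{subject}_{treatment}"
            shift = np.array(
                [2.0 ** effect.get((p, treatment), 0.0) for p in proteins]
            )
            mu = base_abundance * b_subject * shift
            if config.baseline_dispersion > 0:
                shape = 1.0 / config.baseline_dispersion
                lam = rng_c.gamma(shape, mu * config.baseline_dispersion)
            else:
                lam = mu
            counts = rng_c.poisson(lam).astype(float)
            if config.dropout_rate > 0:
                u = rng_d.uniform(size=config.n_proteins)
                mask = u < config.dropout_rate * np.exp(-counts / config.detection_scale)
                counts[mask] = np.nan
            columns[sample_id] = counts
            sample_rows.append(
                {
                    "id": sample_id,
                    "age_group": age,
                    "treatment": treatment,
                    "subject_id": subject,
                    "replicate": 1,
                }
            )
    spc = pd.DataFrame(columns, index=pd.Index(proteins, name="id"))
    samples = pd.DataFrame(sample_rows).set_index("id")
    return SyntheticStudy(spc=spc, samples=samples, proteins=protein_info, truth=truth, config=config)


def simulate_transcriptome(
    config: SimulationConfig,
    timepoints: int = 4,
    frac_concordant: float = 1.0,
    n_participants: int = 24,
    treatment: str | None = None,
    transcript_effect: float = 1.0,
    probe_noise: float = 0.3,
    n_background_genes: int = 1500,
):
    """Generate a paired multi-timepoint expression study tied to the secretome truth.

    Each participant is measured at T1..Tk; a chosen fraction of the genes
    mapped to that ``treatment``'s responsive proteins shift at T2 in the
    direction of the protein's true effect. Every gene carries 2-3 probes
    sharing the gene signal plus probe-specific offset and noise.
    ``n_background_genes`` unmapped genes emulate the rest of the array
    platform: without them the shifted fraction of probes would be large
    enough to distort quantile normalization, which assumes most of the
    measured distribution is unchanged.

    Returns ``(expression, annotation, probe_map, gene_map, truth)`` where
    ``expression`` is probes x samples, ``annotation`` maps samples to
    (participant, timepoint), ``probe_map`` maps probe -> gene,
    ``gene_map`` maps gene -> protein accession and ``truth`` flags the
    concordant genes with their direction.
    """
    if timepoints < 2:
        raise ConfigurationError("timepoints must be >= 2")
    if not 0.0 <= frac_concordant <= 1.0:
        raise ConfigurationError(f"frac_concordant must lie in [0, 1], got {frac_concordant}")
    if treatment is None:
        treatment = config.adjuvants[0] if config.adjuvants else config.treatments[0]
    rng = config.rng("expression")
    rng_struct = config.rng("structure")

    proteins = [f"P{i:05d}" for i in range(config.n_proteins)]
    genes = [f"GENE{i:05d}" for i in range(config.n_proteins)]
    background = [f"BG{i:05d}" for i in range(n_background_genes)]
    gene_map = pd.DataFrame({"source_id": genes, "target_id": proteins})

    truth_spc = _draw_truth(config, rng_struct)
    resp = truth_spc[(truth_spc["treatment"] == treatment) & truth_spc["responsive"]]
    resp_genes = [genes[proteins.index(p)] for p in resp["protein"]]
    resp_dir = {genes[proteins.index(p)]: np.sign(e) or 1.0 for p, e in zip(resp["protein"], resp["true_log2fc"])}

    n_conc = int(round(frac_concordant * len(resp_genes)))
    conc_genes = list(rng.choice(resp_genes, size=n_conc, replace=False)) if n_conc else []
    conc_set = set(conc_genes)

    all_genes = genes + background
    probes, probe_gene = [], []
    for g in all_genes:
        for k in range(int(rng.integers(2, 4))):
            probes.append(f"{g}_at{k}")
            probe_gene.append(g)
    probe_map = pd.DataFrame({"source_id": probes, "target_id": probe_gene})

    gene_base = dict(zip(all_genes, rng.normal(8.0, 1.5, size=len(all_genes))))
    probe_offset = rng.normal(0.0, 0.5, size=len(probes))

    tps = [f"T{k + 1}" for k in range(timepoints)]
    sample_ids, ann_rows = [], []
    data = np.zeros((len(probes), n_participants * timepoints))
    col = 0
    part_effect = rng.normal(0.0, 0.3, size=n_participants)
    base = np.array([gene_base[g] for g in probe_gene]) + probe_offset
    shift_vec = np.array(
        [
            transcript_effect * resp_dir[g] if g in conc_set else 0.0
            for g in probe_gene
        ]
    )
    for p in range(n_participants):
        pid = f"PART{p + 1:02d}"
        for k, tp in enumerate(tps):
            sid = f"{pid}_{tp}"
            vals = base + part_effect[p] + rng.normal(0.0, probe_noise, size=len(probes))
            if tp == "T2":
                vals = vals + shift_vec
            data[:, col] = vals
            sample_ids.append(sid)
            ann_rows.append({"id": sid, "participant": pid, "timepoint": tp})
            col += 1
    expression = pd.DataFrame(data, index=pd.Index(probes, name="id"), columns=sample_ids)
    annotation = pd.DataFrame(ann_rows).set_index("id")
    truth = pd.DataFrame(
        {
            "gene": genes,
            "concordant": [g in conc_set for g in genes],
            "direction": [resp_dir.get(g, 0.0) if g in conc_set else 0.0 for g in genes],
        }
    )
    return expression, annotation, probe_map, gene_map, truth


def simulate_genesets(
    proteins: pd.DataFrame,
    responsive: list[str],
    n_sets: int = 20,
    enriched_set_overlap: float = 1.0,
    set_size: tuple[int, int] = (10, 40),
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets plus one set loaded with responsive proteins.

    The designated set ``responsive_pathway`` contains
    ``round(enriched_set_overlap * len(responsive))`` responsive proteins,
    padded with random non-responsive members up to the mean set size; the
    remaining ``n_sets - 1`` sets are uniform random draws from the
    universe.
    """
    if n_sets < 1:
        raise ConfigurationError("n_sets must be >= 1")
    if not 0.0 <= enriched_set_overlap <= 1.0:
        raise ConfigurationError("enriched_set_overlap must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = list(proteins.index)
    lo, hi = set_size
    sets: dict[str, list[str]] = {}
    n_hit = int(round(enriched_set_overlap * len(responsive)))
    hits = list(rng.choice(responsive, size=n_hit, replace=False)) if n_hit else []
    non_resp = [p for p in universe if p not in set(responsive)]
    pad = max((lo + hi) // 2 - len(hits), 1 if not hits else 0)
    fillers = list(rng.choice(non_resp, size=min(pad, len(non_resp)), replace=False))
    sets["responsive_pathway"] = hits + fillers
    for i in range(n_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        sets[f"random_set_{i + 1:03d}"] = list(rng.choice(universe, size=size, replace=False))
    desc = {name: "synthetic gene set" for name in sets}
    desc["responsive_pathway"] = "synthetic set enriched for responsive proteins"
    return GeneSetCollection(sets, desc)


def write_study(study: SyntheticStudy, out_dir) -> dict[str, str]:
    """Write the fixture TSVs (counts, sample sheet, protein info, truth)."""
    from pathlib import Path

    from .io import write_protein_info, write_sample_sheet, write_spc_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "proteins": out / "proteins.tsv",
        "truth": out / "truth.tsv",
    }
    write_spc_matrix(study.spc, paths["counts"])
    write_sample_sheet(study.samples, paths["samples"])
    write_protein_info(study.proteins, paths["proteins"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
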