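"""Synthetic longitudinal single-nuclei cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two patients biopsied across chemotherapy cycles, negative-binomial
counts with lognormal library sizes, latent archetypes defined by gene-set
programs whose mixing proportions change per cycle, per-pathway linear
drifts of gene log-means across cycles, a patient-level batch shift along a
single gene-space direction, copy-number dosage on contiguous gene blocks
for aneuploid cells, and a masked `not.defined` ploidy subset for the
reclassification stage. Every draw flows from one seed, so identical
configurations reproduce bit-identical cohorts.

Gene log-means compose additively:

    log mu = log baseline + program effect + cycle drift + batch shift
             (+ log CNA dosage for aneuploid cells)

and counts are NB(mean = L * mu, size = r) with a per-cell lognormal
library-size factor L.

Because the temporal stage fits mean log1p-CPM rather than log-means, a
slope planted on log-means induces an attenuated slope on the fitted
response (the log1p curvature at single-cell count depths is not
negligible). ``expected_trend_slopes`` computes the induced response-scale
slope semi-analytically — the exact expectation of the fitted response per
cycle under the generative model (NB pmf summation, Gauss-Hermite
integration over the library-size factor, total counts approximated by
their conditional mean) — and the truth record carries both scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import nbinom

from ._exceptions import ConfigError
from .containers import ExpressionMatrix, GeneSetCollection, validate_metadata
from . import io as atio

N_MT_GENES = 10


def _default_mixing() -> dict[str, list[list[float]]]:
    # Per-cycle archetype proportions shaped like the study's two patients:
    # the responder starts near 50/50, the second archetype peaks at ~0.695
    # by cycle 4 and collapses to ~0.341 by cycle 6; the non-responder stays
    # near 0.69/0.31 across its two cycles.
    responder = [
        [0.50, 0.50],
        [0.44, 0.56],
        [0.37, 0.63],
        [0.305, 0.695],
        [0.48, 0.52],
        [0.659, 0.341],
    ]
    nonresponder = [[0.693, 0.307], [0.643, 0.357]]
    return {"P1": responder, "P2": nonresponder}


def _default_trends() -> dict[str, float]:
    return {
        "TREND_UP_STRONG": 0.02,
        "TREND_UP_WEAK": 0.01,
        "TREND_NULL": 0.0,
        "TREND_DOWN_WEAK": -0.01,
        "TREND_DOWN_STRONG": -0.02,
    }


@dataclass
class SimConfig:
    """Study-shaped cohort parameters. Defaults mirror the modeled study:

    two patients with 6 and 2 cycles, ~1000 cells per biopsy (5-12k cells
    per patient), a 2000-gene panel, NB dispersion size 2, lognormal library
    sizes around 6000 counts (sigma 0.35), two archetypes driven by disjoint
    50-gene programs at 1.0 log-fold, mixing schedules following the
    reported per-cycle archetype proportions, a patient-2 batch shift of
    scale 0.5 along one random gene direction, five 50-gene trend pathways
    with log-mean slopes {+-0.02, +-0.01, 0} per cycle, 80% aneuploid cells
    carrying four 50-gene CNA blocks at dosages 1.5/0.5, and 10% of ploidy
    labels masked to `not.defined`.
    """

    n_patients: int = 2
    cycles_per_patient: tuple[int, ...] = (6, 2)
    cells_per_cycle: int = 1000
    n_genes: int = 2000
    n_archetypes: int = 2
    program_size: int = 50
    program_log_fold: float = 1.0
    mixing_schedule: dict[str, list[list[float]]] | None = None
    trend_slopes: dict[str, float] = field(default_factory=_default_trends)
    trend_set_size: int = 50
    n_null_sets: int = 15
    null_set_size: int = 50
    batch_shift: float = 0.5
    nb_dispersion: float = 2.0
    mean_libsize: float = 6000.0
    libsize_sigma: float = 0.35
    aneuploid_fraction: float = 0.8
    undefined_fraction: float = 0.1
    low_quality_fraction: float = 0.02  # shredded nuclei: ~3% of normal library
    high_mt_fraction: float = 0.02  # stressed nuclei: mitochondrial share ~15%
    cna_segments: tuple[tuple[int, int, float], ...] | None = None  # (start, length, dosage)
    subclone_cna_segments: tuple[tuple[int, int, float], ...] | None = None
    subclone_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mixing_schedule is None:
            if self.n_patients == 2 and self.n_archetypes == 2 and tuple(self.cycles_per_patient) == (6, 2):
                self.mixing_schedule = _default_mixing()
            else:
                self.mixing_schedule = {
                    f"P{p + 1}": [
                        [1.0 / self.n_archetypes] * self.n_archetypes
                        for _ in range(self.cycles_per_patient[p])
                    ]
                    for p in range(self.n_patients)
                }
        if len(self.cycles_per_patient) != self.n_patients:
            raise ConfigError("cycles_per_patient length must equal n_patients")
        for patient, rows in self.mixing_schedule.items():
            for row in rows:
                if abs(sum(row) - 1.0) > 1e-8:
                    raise ConfigError(
                        f"mixing schedule row for {patient} does not sum to 1: {row}"
                    )
                if len(row) != self.n_archetypes:
                    raise ConfigError("mixing schedule width must equal n_archetypes")
        for frac in (self.aneuploid_fraction, self.undefined_fraction, self.subclone_fraction):
            if not (0 <= frac <= 1):
                raise ConfigError("fractions must lie in [0, 1]")
        reserved = (
            self.n_archetypes * self.program_size
            + len(self.trend_slopes) * self.trend_set_size
        )
        if self.cna_segments is None:
            # four contiguous blocks just ahead of the mitochondrial genes
            start = self.n_genes - N_MT_GENES - 400
            if start < reserved:
                raise ConfigError(
                    f"n_genes={self.n_genes} too small: programs and trends reserve "
                    f"{reserved} genes and the default CNA layout needs 400 more "
                    f"before the {N_MT_GENES} mitochondrial genes"
                )
            self.cna_segments = tuple(
                (start + i * 100, 50, dosage) for i, dosage in enumerate([1.5, 0.5, 1.5, 0.5])
            )
        if reserved > self.n_genes - N_MT_GENES:
            raise ConfigError("n_genes too small for the configured program/trend sets")

    @property
    def patients(self) -> list[str]:
        return list(self.mixing_schedule)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a synthetic cohort."""

    archetype: pd.Series  # per-cell archetype label ('none' for diploid cells)
    ploidy: pd.Series  # per-cell true ploidy
    subclone: pd.Series  # per-cell CNA subclone ('none' when not applicable)
    proportions: pd.DataFrame  # realized malignant archetype fractions per patient x cycle
    trend_slopes: dict[str, float]  # planted slopes on gene log-means
    response_slopes: pd.DataFrame | None  # induced slopes of mean log1p-CPM, per patient
    batch_direction: np.ndarray  # gene-space batch shift of the non-reference patients
    gene_baselines: np.ndarray
    program_sets: dict[str, list[str]]


def _gene_names(n_genes: int) -> list[str]:
    names = [f"g{i + 1:05d}" for i in range(n_genes - N_MT_GENES)]
    names += [f"MT-{i + 1}" for i in range(N_MT_GENES)]
    return names


def build_gene_sets(cfg: SimConfig, rng: np.random.Generator):
    """Program, trend and null gene sets over the simulated panel.

    Program and trend sets are disjoint blocks at the front of the panel;
    null sets are random draws from the remaining genes.
    """
    names = _gene_names(cfg.n_genes)
    cursor = 0
    sets: dict[str, list[str]] = {}
    program_sets: dict[str, list[str]] = {}
    for a in range(cfg.n_archetypes):
        block = names[cursor : cursor + cfg.program_size]
        cursor += cfg.program_size
        program_sets[f"PROGRAM_A{a + 1}"] = block
        sets[f"PROGRAM_A{a + 1}"] = block
    for trend_name in cfg.trend_slopes:
        block = names[cursor : cursor + cfg.trend_set_size]
        cursor += cfg.trend_set_size
        sets[trend_name] = block
    cna_genes = {
        i for start, length, _ in cfg.cna_segments for i in range(start, start + length)
    }
    free = [i for i in range(cursor, cfg.n_genes - N_MT_GENES) if i not in cna_genes]
    for j in range(cfg.n_null_sets):
        idx = rng.choice(len(free), size=cfg.null_set_size, replace=False)
        sets[f"NULL_{j + 1:02d}"] = [names[free[i]] for i in sorted(idx)]
    return GeneSetCollection(sets, source="synthetic"), program_sets


def generate_cohort(cfg: SimConfig | None = None):
    """Simulate a cohort; returns (expr, metadata, gene_sets, truth)."""
    cfg = cfg or SimConfig()
    root = np.random.SeedSequence(cfg.seed)
    seq_structure, seq_sets, seq_counts, seq_mask = root.spawn(4)
    rng = np.random.default_rng(seq_structure)

    gene_names = _gene_names(cfg.n_genes)
    baselines = rng.lognormal(0.0, 1.0, cfg.n_genes)
    # mitochondrial genes get a fixed ~2% share of the library
    mt_total = 0.02 / 0.98 * baselines[:-N_MT_GENES].sum()
    baselines[-N_MT_GENES:] = mt_total / N_MT_GENES
    baselines *= cfg.mean_libsize / baselines.sum()
    # per-gene batch offsets are N(0, batch_shift^2): the scale is a per-gene
    # log-fold sd, large enough to reorder within-cell ranks as real
    # library-chemistry differences do
    batch_direction = rng.normal(0.0, 1.0, cfg.n_genes)

    gene_sets, program_sets = build_gene_sets(cfg, np.random.default_rng(seq_sets))
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    program_idx = {
        a: np.array([gene_pos[g] for g in program_sets[f"PROGRAM_A{a + 1}"]])
        for a in range(cfg.n_archetypes)
    }
    trend_idx = {
        name: np.array([gene_pos[g] for g in gene_sets.sets[name]])
        for name in cfg.trend_slopes
    }

    dosage_main = np.ones(cfg.n_genes)
    for start, length, dose in cfg.cna_segments:
        dosage_main[start : start + length] = dose
    dosage_alt = None
    if cfg.subclone_cna_segments is not None:
        dosage_alt = np.ones(cfg.n_genes)
        for start, length, dose in cfg.subclone_cna_segments:
            dosage_alt[start : start + length] = dose

    rng_counts = np.random.default_rng(seq_counts)
    r = cfg.nb_dispersion
    blocks, cell_ids, meta_rows = [], [], []
    truth_arch, truth_ploidy, truth_sub = [], [], []

    for p_i, patient in enumerate(cfg.patients):
        shift = cfg.batch_shift * batch_direction if p_i > 0 else 0.0
        log_base = np.log(baselines) + shift
        for cycle in range(1, cfg.cycles_per_patient[p_i] + 1):
            n = cfg.cells_per_cycle
            mix = np.asarray(cfg.mixing_schedule[patient][cycle - 1])
            aneuploid = rng_counts.random(n) < cfg.aneuploid_fraction
            arch = np.full(n, -1)
            arch[aneuploid] = rng_counts.choice(
                cfg.n_archetypes, size=int(aneuploid.sum()), p=mix
            )
            subclone = np.full(n, -1)
            if dosage_alt is not None:
                alt = rng_counts.random(n) < cfg.subclone_fraction
                subclone[aneuploid] = 0
                subclone[aneuploid & alt] = 1

            log_mu = np.tile(log_base, (n, 1))
            for a, idx in program_idx.items():
                rows = np.flatnonzero(arch == a)
                if rows.size:
                    log_mu[np.ix_(rows, idx)] += cfg.program_log_fold
            for name, slope in cfg.trend_slopes.items():
                if slope:
                    log_mu[:, trend_idx[name]] += slope * (cycle - 1)
            mu = np.exp(log_mu)
            mu[aneuploid] *= dosage_main
            if dosage_alt is not None:
                alt_rows = subclone == 1
                mu[alt_rows] = np.exp(log_mu[alt_rows]) * dosage_alt
            lib = rng_counts.lognormal(
                -cfg.libsize_sigma**2 / 2, cfg.libsize_sigma, n
            )
            lowq = rng_counts.random(n) < cfg.low_quality_fraction
            lib[lowq] *= 0.03
            himt = rng_counts.random(n) < cfg.high_mt_fraction
            mu[himt, -N_MT_GENES:] *= 8.0
            lam = lib[:, None] * mu
            counts = rng_counts.negative_binomial(r, r / (r + lam))
            blocks.append(sp.csr_matrix(counts))

            ids = [f"{patient}_c{cycle}_{i:05d}" for i in range(n)]
            cell_ids.extend(ids)
            n_feat = (counts > 0).sum(axis=1)
            pct_mt = 100.0 * counts[:, -N_MT_GENES:].sum(axis=1) / np.maximum(
                counts.sum(axis=1), 1
            )
            site = "site_A" if cycle % 2 else "site_B"
            for i, cid in enumerate(ids):
                meta_rows.append(
                    {
                        "cell_id": cid,
                        "patient": patient,
                        "cycle": cycle,
                        "biopsy_site": site,
                        "cell_type": "epithelial",
                        "ploidy": "aneuploid" if aneuploid[i] else "diploid",
                        "n_features": int(n_feat[i]),
                        "pct_mt": float(pct_mt[i]),
                    }
                )
            truth_arch.extend(
                f"A{arch[i] + 1}" if aneuploid[i] else "none" for i in range(n)
            )
            truth_ploidy.extend(
                "aneuploid" if aneuploid[i] else "diploid" for i in range(n)
            )
            truth_sub.extend(
                f"S{subclone[i] + 1}" if subclone[i] >= 0 else "none" for i in range(n)
            )

    expr = ExpressionMatrix(sp.vstack(blocks), gene_names, cell_ids, layer="counts")
    meta = pd.DataFrame(meta_rows)

    rng_mask = np.random.default_rng(seq_mask)
    masked = rng_mask.random(len(meta)) < cfg.undefined_fraction
    meta.loc[masked, "ploidy"] = "not.defined"
    meta = validate_metadata(meta)

    truth_arch = pd.Series(truth_arch, index=cell_ids, name="archetype_true")
    truth_ploidy = pd.Series(truth_ploidy, index=cell_ids, name="ploidy_true")
    truth_sub = pd.Series(truth_sub, index=cell_ids, name="subclone_true")
    malignant = truth_ploidy.eq("aneuploid")
    prop = (
        pd.DataFrame(
            {
                "patient": meta["patient"].to_numpy(),
                "cycle": meta["cycle"].to_numpy(),
                "archetype": truth_arch.to_numpy(),
            }
        )[malignant.to_numpy()]
        .groupby(["patient", "cycle", "archetype"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    prop["proportion"] = prop["n"] / prop.groupby(["patient", "cycle"], observed=True)[
        "n"
    ].transform("sum")

    truth = TruthRecord(
        archetype=truth_arch,
        ploidy=truth_ploidy,
        subclone=truth_sub,
        proportions=prop,
        trend_slopes=dict(cfg.trend_slopes),
        response_slopes=None,
        batch_direction=batch_direction,
        gene_baselines=baselines,
        program_sets=program_sets,
    )
    return expr, meta, gene_sets, truth


def _expected_log1p_cpm(mu, total, sigma, r, scale_total=1e4, gh_nodes=21):
    """E[mean_g log1p(scale * X_g / (L * total))] with X_g ~ NB(L*mu_g, r).

    Library-size factor L is lognormal(-sigma^2/2, sigma), integrated by
    Gauss-Hermite; total counts are approximated by their conditional mean
    L * total. Exact NB expectation by pmf summation.
    """
    nodes, wts = hermegauss(gh_nodes)
    wts = wts / wts.sum()
    out = 0.0
    for z, w in zip(nodes, wts):
        L = np.exp(-sigma**2 / 2 + sigma * z)
        s = scale_total / (L * total)
        mus = L * np.asarray(mu)
        kmax = int(np.max(mus + 12 * np.sqrt(mus + mus**2 / r))) + 5
        k = np.arange(kmax + 1)
        pmf = nbinom.pmf(k[None, :], r, r / (r + mus[:, None]))
        out += w * float(np.mean(pmf @ np.log1p(s * k)))
    return out


def expected_trend_slopes(cfg: SimConfig, truth: TruthRecord) -> pd.DataFrame:
    """Induced response-scale slope per trend pathway and patient.

    The temporal stage fits mean log1p-CPM over a pathway's genes; because
    OLS is linear in the response, the fitted slope is exactly unbiased for
    the OLS slope of the per-cycle *expected* response. This computes that
    expectation for each cycle — mixing over archetype/ploidy cell classes
    with their configured weights — and regresses it on the cycle number.
    """
    gene_names = _gene_names(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    baselines = truth.gene_baselines
    program_idx = {
        a: np.array([gene_pos[g] for g in truth.program_sets[f"PROGRAM_A{a + 1}"]])
        for a in range(cfg.n_archetypes)
    }
    dosage = np.ones(cfg.n_genes)
    for start, length, dose in cfg.cna_segments:
        dosage[start : start + length] = dose

    trend_sets = {}
    cursor = cfg.n_archetypes * cfg.program_size
    for name in cfg.trend_slopes:
        trend_sets[name] = np.arange(cursor, cursor + cfg.trend_set_size)
        cursor += cfg.trend_set_size

    rows = []
    for p_i, patient in enumerate(cfg.patients):
        cycles = np.arange(1, cfg.cycles_per_patient[p_i] + 1)
        shift = cfg.batch_shift * truth.batch_direction if p_i > 0 else 0.0
        expected = {name: [] for name in cfg.trend_slopes}
        for cycle in cycles:
            mix = np.asarray(cfg.mixing_schedule[patient][cycle - 1])
            log_mu0 = np.log(baselines) + shift
            for name, slope in cfg.trend_slopes.items():
                log_mu0[trend_sets[name]] += slope * (cycle - 1)
            # cell classes: (archetype a, aneuploid) and (no program, diploid)
            classes = []
            for a in range(cfg.n_archetypes):
                lm = log_mu0.copy()
                lm[program_idx[a]] += cfg.program_log_fold
                classes.append((cfg.aneuploid_fraction * mix[a], np.exp(lm) * dosage))
            if cfg.aneuploid_fraction < 1:
                classes.append((1 - cfg.aneuploid_fraction, np.exp(log_mu0)))
            for name, idx in trend_sets.items():
                val = 0.0
                for weight, mu in classes:
                    if weight:
                        val += weight * _expected_log1p_cpm(
                            mu[idx], mu.sum(), cfg.libsize_sigma, cfg.nb_dispersion
                        )
                expected[name].append(val)
        if len(cycles) >= 2:
            for name, vals in expected.items():
                slope = np.polyfit(cycles, vals, 1)[0]
                rows.append(
                    {
                        "patient": patient,
                        "pathway": name,
                        "planted_logmean_slope": cfg.trend_slopes[name],
                        "response_slope": float(slope),
                    }
                )
    return pd.DataFrame(rows)


def write_cohort(bundle, out_dir, overwrite: bool = False) -> dict[str, str]:
    """Persist a generated cohort in the package's on-disk formats."""
    expr, meta, gene_sets, truth = bundle
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
        "metadata": out / "metadata.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth_cells": out / "truth_cells.tsv",
        "truth_proportions": out / "truth_proportions.tsv",
        "truth_slopes": out / "truth_slopes.json",
    }
    atio.write_counts(expr, paths["matrix"], paths["genes"], paths["cells"])
    atio.write_metadata(meta, paths["metadata"])
    atio.write_gmt(gene_sets, paths["gene_sets"])
    truth_cells = pd.DataFrame(
        {
            "cell_id": truth.archetype.index,
            "archetype_true": truth.archetype.to_numpy(),
            "ploidy_true": truth.ploidy.to_numpy(),
            "subclone_true": truth.subclone.to_numpy(),
        }
    )
    truth_cells.to_csv(paths["truth_cells"], sep="\t", index=False)
    truth.proportions.to_csv(paths["truth_proportions"], sep="\t", index=False)
    paths["truth_slopes"].write_text(json.dumps(truth.trend_slopes, indent=1))
    return {k: str(v) for k, v in paths.items()}
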