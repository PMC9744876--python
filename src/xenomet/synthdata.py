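"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: dual-species
negative-binomial count matrices with planted per-gene cross-mapping
rates and species-pure controls, single-cell matrices with a shifted
signature, survival cohorts whose hazard depends on a planted score,
piecewise-exponential tumor-burden trajectories with planted resistance
crossings, and paired variant tables where decoys each violate one named
filter criterion.

All generators are deterministic for a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from xenomet.endpoints import BurdenSeries
from xenomet.variants import (
    CONTROL,
    RESISTANT,
    SampleCall,
    VariantRecord,
)
from xenomet.xenofilter import (
    HUMAN,
    HUMAN_ONLY,
    MOUSE,
    MOUSE_ONLY,
    XENOGRAFT,
    DualSpeciesCounts,
)


@dataclass
class SimConfig:
    """Parameters for every generator; unused fields are ignored by each.

    The same config + seed always yields byte-identical outputs.
    """

    seed: int = 0

    # dual-species counts
    n_human_genes: int = 500
    n_mouse_genes: int = 500
    n_xeno: int = 4
    n_human_ctrl: int = 2
    n_mouse_ctrl: int = 2
    dispersion: float = 0.1  # NB variance = mu + dispersion * mu^2; 0 -> Poisson
    lib_size: float = 2e6  # expected reads on a species' genes per library
    stroma_ratio: float = 1.0  # mouse library size relative to human, in xenografts
    n_contaminated: int = 0  # contaminated genes picked deterministically if ids not given
    contaminated_gene_ids: frozenset[str] | None = None
    crossmap_rates: Mapping[str, float] | None = None  # explicit per-gene rates
    contam_fraction: float = 0.3  # target cross-mapped fraction for planted genes
    clean_fraction: float = 0.005  # and for everything else

    # signature / single-cell / survival
    sig_genes: tuple[str, ...] = tuple(f"SIG{i:03d}" for i in range(1, 21))
    sig_effect: float = 1.0  # log2 expression shift
    n_sc_background_genes: int = 80
    n_cells_per_group: int = 200
    sc_base_mean: float = 5.0
    hazard_ratio: float = 2.0
    n_patients: int = 100
    cohort_noise_sd: float = 0.3  # per-gene expression noise around the latent score
    base_hazard: float = 0.02  # events per day for the low stratum
    censor_horizon: float = 365.0
    dropout_rate: float = 0.002  # independent exponential censoring

    # burden trajectories
    n_animals: int = 20
    n_timepoints: int = 20
    imaging_interval: float = 3.0  # days between observations
    treatment_start_day: float = 9.0
    growth_rate: float = 0.25  # per day, > 0
    regression_rate: float = -0.15  # per day, < 0
    resistance_latency: float = 15.0  # days of regression before regrowth
    resistant_fraction: float = 0.5
    initial_burden: float = 1e5
    burden_noise_sigma: float = 0.1  # lognormal measurement noise

    # variant tables
    n_variants: int = 30
    n_true_persistent: int = 5

    def validate(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0.0 <= self.resistant_fraction <= 1.0):
            raise ValueError("resistant_fraction must be in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.n_true_persistent > self.n_variants:
            raise ValueError("n_true_persistent exceeds n_variants")
        for frac in (self.contam_fraction, self.clean_fraction):
            if not (0.0 <= frac < 1.0):
                raise ValueError("contamination fractions must be in [0, 1)")


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _gene_ids(cfg: SimConfig) -> tuple[list[str], list[str]]:
    human = [f"HG{i:06d}" for i in range(1, cfg.n_human_genes + 1)]
    mouse = [f"MG{i:06d}" for i in range(1, cfg.n_mouse_genes + 1)]
    return human, mouse


def planted_contaminated_ids(cfg: SimConfig) -> frozenset[str]:
    """The gene ids planted as contaminated (explicit set, or the first
    ``n_contaminated`` ids split evenly across species)."""
    if cfg.contaminated_gene_ids is not None:
        return frozenset(cfg.contaminated_gene_ids)
    human, mouse = _gene_ids(cfg)
    n_h = cfg.n_contaminated // 2 + cfg.n_contaminated % 2
    n_m = cfg.n_contaminated // 2
    return frozenset(human[:n_h]) | frozenset(mouse[:n_m])


def gen_dual_species_counts(
    cfg: SimConfig,
) -> tuple[DualSpeciesCounts, pd.DataFrame]:
    """Simulate a dual-species count matrix with planted cross-mapping.

    True counts are negative binomial around per-gene means; cross-mapped
    reads into a gene are Poisson with intensity (per-gene rate) x
    (opposite-species library size).  Planted rates are set so the
    expected cross-mapped fraction of observed reads is
    ``contam_fraction`` for contaminated genes and ``clean_fraction``
    otherwise, unless explicit ``crossmap_rates`` are supplied.

    Returns the counts plus a long truth table with one row per
    (gene, xenograft sample): true, cross-mapped, and observed counts
    (observed = true + cross-mapped exactly), the planted rate, and the
    contaminated flag.
    """
    cfg.validate()
    if cfg.n_human_ctrl < 1 or cfg.n_mouse_ctrl < 1:
        raise ValueError("need at least one control library of each species")
    rng = np.random.default_rng(cfg.seed)
    human, mouse = _gene_ids(cfg)
    contaminated = planted_contaminated_ids(cfg)

    # per-gene expression means summing to lib_size per species
    def _means(n: int) -> np.ndarray:
        w = rng.lognormal(0.0, 1.0, size=n)
        return cfg.lib_size * w / w.sum()

    mu_h = pd.Series(_means(cfg.n_human_genes), index=human)
    mu_m = pd.Series(_means(cfg.n_mouse_genes), index=mouse)

    # planted rates: expected cross-mapped reads = f/(1-f) * gene mean, so the
    # expected cross-mapped fraction of observed reads is f
    exp_opp_total = {HUMAN: cfg.lib_size * cfg.stroma_ratio, MOUSE: cfg.lib_size}
    rates = pd.Series(0.0, index=human + mouse)
    if cfg.crossmap_rates is not None:
        for g, r in cfg.crossmap_rates.items():
            rates[g] = r
    else:
        for species, mu in ((HUMAN, mu_h), (MOUSE, mu_m)):
            f = np.where(
                mu.index.isin(contaminated), cfg.contam_fraction, cfg.clean_fraction
            )
            rates[mu.index] = (f / (1.0 - f)) * mu.to_numpy() / exp_opp_total[species]

    samples = (
        [f"xeno{i}" for i in range(1, cfg.n_xeno + 1)]
        + [f"hctrl{i}" for i in range(1, cfg.n_human_ctrl + 1)]
        + [f"mctrl{i}" for i in range(1, cfg.n_mouse_ctrl + 1)]
    )
    classes = (
        [XENOGRAFT] * cfg.n_xeno
        + [HUMAN_ONLY] * cfg.n_human_ctrl
        + [MOUSE_ONLY] * cfg.n_mouse_ctrl
    )

    counts = pd.DataFrame(0, index=human + mouse, columns=samples, dtype=np.int64)
    truth_rows = []
    for sample, cls in zip(samples, classes):
        true_h = np.zeros(cfg.n_human_genes, dtype=np.int64)
        true_m = np.zeros(cfg.n_mouse_genes, dtype=np.int64)
        if cls in (XENOGRAFT, HUMAN_ONLY):
            true_h = _nb_draws(rng, mu_h.to_numpy(), cfg.dispersion)
        if cls in (XENOGRAFT, MOUSE_ONLY):
            true_m = _nb_draws(
                rng, mu_m.to_numpy() * (cfg.stroma_ratio if cls == XENOGRAFT else 1.0),
                cfg.dispersion,
            )
        # cross-mapping intensity uses the realized same-species totals
        cross_h = rng.poisson(rates[human].to_numpy() * true_m.sum())
        cross_m = rng.poisson(rates[mouse].to_numpy() * true_h.sum())
        counts[sample] = np.concatenate([true_h + cross_h, true_m + cross_m])
        if cls == XENOGRAFT:
            truth_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": human + mouse,
                        "sample_id": sample,
                        "true_count": np.concatenate([true_h, true_m]),
                        "crossmapped_count": np.concatenate([cross_h, cross_m]),
                    }
                )
            )

    truth = pd.concat(truth_rows, ignore_index=True)
    truth["observed_count"] = truth["true_count"] + truth["crossmapped_count"]
    truth["rate"] = rates.loc[truth["gene_id"]].to_numpy()
    truth["contaminated"] = truth["gene_id"].isin(contaminated)
    planted_mean = pd.concat([mu_h, mu_m * cfg.stroma_ratio])
    truth["planted_mean"] = planted_mean.loc[truth["gene_id"]].to_numpy()

    gene_info = pd.DataFrame(
        {
            "species": [HUMAN] * cfg.n_human_genes + [MOUSE] * cfg.n_mouse_genes,
            "length_bp": np.full(cfg.n_human_genes + cfg.n_mouse_genes, 1000),
        },
        index=human + mouse,
    )
    sample_info = pd.DataFrame({"class": classes}, index=samples)
    return DualSpeciesCounts(counts, gene_info, sample_info), truth


def gen_single_cell_matrix(cfg: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a cells x genes count matrix with two groups.

    Cells in the ``progressive`` group have the signature genes' mean
    multiplied by 2**sig_effect.  Returns the matrix and per-cell group
    labels.
    """
    cfg.validate()
    if not cfg.sig_genes:
        raise ValueError("empty signature")
    if cfg.n_cells_per_group < 2:
        raise ValueError("need at least 2 cells per group")
    rng = np.random.default_rng(cfg.seed + 1)
    genes = list(cfg.sig_genes) + [
        f"BG{i:04d}" for i in range(1, cfg.n_sc_background_genes + 1)
    ]
    n_genes = len(genes)
    labels = ["control"] * cfg.n_cells_per_group + ["progressive"] * cfg.n_cells_per_group
    cells = [f"cell{i:05d}" for i in range(1, len(labels) + 1)]

    base = np.full(n_genes, cfg.sc_base_mean)
    shifted = base.copy()
    shifted[: len(cfg.sig_genes)] *= 2.0**cfg.sig_effect
    rows = np.empty((len(cells), n_genes), dtype=np.int64)
    for i, lab in enumerate(labels):
        mu = shifted if lab == "progressive" else base
        rows[i] = _nb_draws(rng, mu, cfg.dispersion)
    matrix = pd.DataFrame(rows, index=cells, columns=genes)
    return matrix, pd.Series(labels, index=cells, name="group")


def gen_survival_cohort(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an expression matrix plus survival table.

    Each patient carries a latent signature level; signature-gene
    expression (on a normalized log scale) is shifted by
    ``sig_effect`` x level.  Event times are exponential, with the hazard
    multiplied by ``hazard_ratio`` for patients whose latent level is
    above the cohort median.  Censoring is administrative at
    ``censor_horizon`` plus independent exponential dropout.

    Returns (gene x patient expression, survival table with columns
    unit_id/time/event, truth table with the latent level and planted
    stratum).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_patients
    patients = [f"P{i:04d}" for i in range(1, n + 1)]
    genes = list(cfg.sig_genes) + [
        f"BG{i:04d}" for i in range(1, cfg.n_sc_background_genes + 1)
    ]
    latent = rng.standard_normal(n)
    expr = rng.normal(5.0, cfg.cohort_noise_sd, size=(len(genes), n))
    expr[: len(cfg.sig_genes), :] += cfg.sig_effect * latent[None, :]
    expression = pd.DataFrame(expr, index=genes, columns=patients)

    planted_high = latent > np.median(latent)
    hazard = cfg.base_hazard * np.where(planted_high, cfg.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    dropout = (
        rng.exponential(1.0 / cfg.dropout_rate, size=n)
        if cfg.dropout_rate > 0
        else np.full(n, np.inf)
    )
    censor_time = np.minimum(dropout, cfg.censor_horizon)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    survival = pd.DataFrame({"unit_id": patients, "time": time, "event": event})
    truth = pd.DataFrame(
        {"unit_id": patients, "latent": latent, "planted_high": planted_high}
    )
    return expression, survival, truth


def _noise_free_burden(cfg: SimConfig, times: np.ndarray, resistant: bool) -> np.ndarray:
    ts = cfg.treatment_start_day
    t_regrow = ts + cfg.resistance_latency
    b = np.empty_like(times)
    pre = times <= ts
    b[pre] = cfg.initial_burden * np.exp(cfg.growth_rate * times[pre])
    b_ts = cfg.initial_burden * np.exp(cfg.growth_rate * ts)
    decl = (~pre) & (times <= t_regrow if resistant else np.ones_like(pre))
    b[decl] = b_ts * np.exp(cfg.regression_rate * (times[decl] - ts))
    if resistant:
        regrow = times > t_regrow
        b_nadir = b_ts * np.exp(cfg.regression_rate * cfg.resistance_latency)
        b[regrow] = b_nadir * np.exp(cfg.growth_rate * (times[regrow] - t_regrow))
    return b


def _planted_crossings(
    cfg: SimConfig, times: np.ndarray, clean: np.ndarray
) -> tuple[float | None, float | None]:
    """Planted resistance and progression days from the noise-free series.

    Both rules are evaluated on the noise-free grid directly: resistance
    at the first post-treatment timepoint with burden >= 10x the running
    post-treatment minimum; progression at the first post-treatment
    timepoint with burden >= 2x the last pre-treatment value.
    """
    ts = cfg.treatment_start_day
    baseline = clean[times <= ts][-1]
    post = times > ts
    nadir = np.inf
    resist_day = None
    for day, b in zip(times[post], clean[post]):
        nadir = min(nadir, b)
        if resist_day is None and b >= 10.0 * nadir:
            resist_day = float(day)
    pfs_day = None
    for day, b in zip(times[post], clean[post]):
        if b >= 2.0 * baseline:
            pfs_day = float(day)
            break
    return resist_day, pfs_day


def gen_burden_trajectories(
    cfg: SimConfig,
) -> tuple[list[BurdenSeries], pd.DataFrame]:
    """Simulate piecewise-exponential tumor-burden trajectories.

    Burden grows exponentially pre-treatment and regresses afterwards; a
    ``resistant_fraction`` of animals resume growth after a fixed
    latency.  Measurements carry multiplicative lognormal noise
    (``burden_noise_sigma``; 0 for noise-free).  The truth table records
    each animal's resistance status and the planted crossing days for
    the resistance (10x running nadir) and progression (2x last
    pre-treatment burden) rules on the noise-free series.
    """
    cfg.validate()
    if cfg.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    if cfg.growth_rate <= 0:
        raise ValueError("growth_rate must be > 0")
    if cfg.regression_rate >= 0:
        raise ValueError("regression_rate must be < 0")
    rng = np.random.default_rng(cfg.seed + 3)
    times = np.arange(cfg.n_timepoints, dtype=float) * cfg.imaging_interval

    n_res = int(round(cfg.resistant_fraction * cfg.n_animals))
    resistant_flags = np.zeros(cfg.n_animals, dtype=bool)
    resistant_flags[rng.choice(cfg.n_animals, size=n_res, replace=False)] = True

    series_list: list[BurdenSeries] = []
    truth_rows = []
    for i in range(cfg.n_animals):
        animal = f"A{i + 1:03d}"
        clean = _noise_free_burden(cfg, times, bool(resistant_flags[i]))
        noise = (
            rng.lognormal(0.0, cfg.burden_noise_sigma, size=times.size)
            if cfg.burden_noise_sigma > 0
            else np.ones_like(times)
        )
        series_list.append(
            BurdenSeries(
                animal_id=animal,
                time=times.copy(),
                burden=clean * noise,
                treatment_start=cfg.treatment_start_day,
                compartment="cranial",
            )
        )
        resist_day, pfs_day = _planted_crossings(cfg, times, clean)
        truth_rows.append(
            {
                "animal_id": animal,
                "resistant": bool(resistant_flags[i]),
                "planted_resistance_day": resist_day,
                "planted_pfs_day": pfs_day,
            }
        )
    return series_list, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# variant tables

#: decoy criteria, in the order they are cycled through.  alt_resistant and
#: nraf_resistant violations force a delta_nraf violation too (the thresholds
#: make a single-criterion violation logically impossible there); every other
#: decoy violates exactly its assigned criterion.
DECOY_CRITERIA: tuple[str, ...] = (
    "not_damaging",
    "vqsr",
    "maf",
    "gq",
    "mq",
    "pldiff_dp",
    "lcr",
    "dp_control",
    "dp_resistant",
    "alt_resistant",
    "ref_control",
    "nraf_resistant",
    "delta_nraf",
    "rol",
    "rpkm",
)


def _passing_record(idx: int, gene: str) -> VariantRecord:
    """A record that passes every filter criterion with margin."""
    return VariantRecord(
        chrom=f"chr{(idx % 22) + 1}",
        pos=1000 + idx * 137,
        ref="A",
        alt="T",
        gene=gene,
        consequence="LoF",
        metasvm_deleterious=True,
        vqsr_pass=True,
        gnomad_maf=0.0,
        lcr=False,
        samples={
            CONTROL: SampleCall(dp=40, alt_reads=0, ref_reads=40),
            RESISTANT: SampleCall(dp=40, alt_reads=20, ref_reads=20),
        },
        present_in_rol=(True, True, True, True),
    )


def _apply_decoy(rec: VariantRecord, criterion: str) -> VariantRecord:
    """Violate one named criterion, leaving the others passing."""
    s = dict(rec.samples)
    if criterion == "not_damaging":
        rec.consequence = "missense"
        rec.metasvm_deleterious = False
    elif criterion == "vqsr":
        rec.vqsr_pass = False
    elif criterion == "maf":
        rec.gnomad_maf = 1e-3
    elif criterion == "gq":
        s[CONTROL] = replace(s[CONTROL], gq=10.0)
    elif criterion == "mq":
        s[RESISTANT] = replace(s[RESISTANT], mq=30.0)
    elif criterion == "pldiff_dp":
        s[CONTROL] = replace(s[CONTROL], pl_diff=100.0)  # 100/40 = 2.5 < 8
    elif criterion == "lcr":
        rec.lcr = True
    elif criterion == "dp_control":
        s[CONTROL] = SampleCall(dp=10, alt_reads=0, ref_reads=10)  # > dp_min, <= 11
    elif criterion == "dp_resistant":
        s[RESISTANT] = SampleCall(dp=10, alt_reads=5, ref_reads=5)  # NRAF 0.5 intact
    elif criterion == "alt_resistant":
        s[RESISTANT] = SampleCall(dp=12, alt_reads=2, ref_reads=10)  # NRAF 0.167
    elif criterion == "ref_control":
        s[CONTROL] = SampleCall(dp=40, alt_reads=0, ref_reads=2)  # NRAF_C still 0
    elif criterion == "nraf_resistant":
        s[RESISTANT] = SampleCall(dp=100, alt_reads=15, ref_reads=85)  # NRAF 0.15
    elif criterion == "delta_nraf":
        s[CONTROL] = SampleCall(dp=40, alt_reads=12, ref_reads=28)  # delta 0.5-0.3
    elif criterion == "rol":
        rec.present_in_rol = (True, True, True, False)
    elif criterion == "rpkm":
        pass  # handled through the RPKM table
    else:
        raise ValueError(f"unknown decoy criterion {criterion!r}")
    rec.samples = s
    return rec


def gen_variant_table(
    cfg: SimConfig,
) -> tuple[list[VariantRecord], pd.DataFrame, pd.DataFrame]:
    """Generate a paired variant table with planted persistent variants.

    The first ``n_true_persistent`` records pass every filter criterion
    with margin; the remaining records are decoys, each violating the
    next criterion in :data:`DECOY_CRITERIA` (cycled).  Returns the
    records, a truth table (variant_id, planted flag, assigned
    criterion), and a gene x sample RPKM table sized so the expression
    gate passes for every gene except the ``rpkm`` decoys' genes.
    """
    cfg.validate()
    records: list[VariantRecord] = []
    truth_rows = []
    rpkm_values: dict[str, float] = {}
    n_decoys = cfg.n_variants - cfg.n_true_persistent
    for i in range(cfg.n_variants):
        gene = f"VGENE{i + 1:04d}"
        rec = _passing_record(i, gene)
        if i < cfg.n_true_persistent:
            criterion = None
            rpkm_values[gene] = 50.0
        else:
            criterion = DECOY_CRITERIA[(i - cfg.n_true_persistent) % len(DECOY_CRITERIA)]
            rec = _apply_decoy(rec, criterion)
            rpkm_values[gene] = 5.0 if criterion == "rpkm" else 50.0
        records.append(rec)
        truth_rows.append(
            {
                "variant_id": rec.variant_id,
                "planted_persistent": criterion is None,
                "assigned_criterion": criterion or "",
            }
        )
    truth = pd.DataFrame(truth_rows)
    genes = [f"VGENE{i + 1:04d}" for i in range(cfg.n_variants)]
    rpkm_table = pd.DataFrame(
        {f"S{j}": [rpkm_values[g] for g in genes] for j in range(1, 5)}, index=genes
    )
    assert n_decoys >= 0
    return records, truth, rpkm_table
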