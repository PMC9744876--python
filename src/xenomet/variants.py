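"""Two-stage somatic variant filtering.

Stage one keeps damaging, well-supported calls (loss-of-function or
predicted-deleterious missense; caller PASS; rare in the population;
depth/quality gates; outside low-complexity regions).  Stage two keeps
variants that newly persist in the resistant sample relative to its
paired control (depth, alt/ref support, allele-frequency level and
shift, and presence in all late in-vivo replicates), then gates on gene
expression (mean RPKM).

All annotation-time quantities (VQSR status, population frequency,
deleteriousness calls, PL differences, low-complexity flags, replicate
presence) are consumed as input columns, never recomputed.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import pandas as pd

#: key of the paired control sample in ``VariantRecord.samples``
CONTROL = "control"
#: key of the paired resistant sample
RESISTANT = "resistant"

LOF = "LoF"
MISSENSE = "missense"


@dataclass
class SampleCall:
    """Per-sample read support and genotype quality at one variant site."""

    dp: int
    alt_reads: int
    ref_reads: int
    gq: float = 99.0
    mq: float = 60.0
    pl_diff: float = 1e6  # difference of the two smallest PLs (annotation-time)

    def __post_init__(self) -> None:
        if self.dp < 0 or self.alt_reads < 0 or self.ref_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads + self.ref_reads > self.dp:
            raise ValueError("alt + ref reads exceed depth")


@dataclass
class VariantRecord:
    """One candidate variant with per-sample support and annotation flags."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    consequence: str  # LoF / missense / other
    metasvm_deleterious: bool
    vqsr_pass: bool
    gnomad_maf: float
    lcr: bool
    samples: dict[str, SampleCall]
    present_in_rol: tuple[bool, ...] = (False, False, False, False)
    genotype: str = "het"  # het / hom (used by the recessive preset)
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not (0.0 <= self.gnomad_maf <= 1.0):
            raise ValueError("gnomad_maf must be in [0, 1]")
        if not self.variant_id:
            self.variant_id = f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class FilterConfig:
    """Thresholds for both filter stages.

    ``*_excl`` thresholds are strict (value must exceed them); the
    quality-stage thresholds are inclusive as named.
    """

    maf_max: float = 2e-5
    dp_min: int = 8
    gq_min: float = 20.0
    mq_min: float = 40.0
    pldiff_dp_min: float = 8.0
    dp_paired_excl: int = 11  # depth must be > this in both paired samples
    alt_r_excl: int = 2  # resistant alt reads must be > this
    ref_c_excl: int = 2  # control ref reads must be > this
    nraf_r_excl: float = 0.15
    delta_nraf_excl: float = 0.25
    rol_required: int = 4
    rpkm_excl: float = 10.0
    require_homozygous_or_comphet: bool = False


def dominant_config() -> FilterConfig:
    """Rare-dominant preset (the default thresholds)."""
    return FilterConfig()


def recessive_config() -> FilterConfig:
    """Rare-recessive preset: relaxed MAF plus a zygosity requirement."""
    return FilterConfig(maf_max=1e-3, require_homozygous_or_comphet=True)


def nraf(record: VariantRecord, sample: str) -> float:
    """Non-reference allele frequency: alt reads / depth in one sample."""
    call = record.samples[sample]
    if call.dp == 0:
        raise ValueError(f"DP is 0 for sample {sample!r} at {record.variant_id}")
    return call.alt_reads / call.dp


def _is_damaging(record: VariantRecord) -> bool:
    if record.consequence == LOF:
        return True
    return record.consequence == MISSENSE and record.metasvm_deleterious


def _quality_failure(record: VariantRecord, cfg: FilterConfig) -> str | None:
    """First failing quality criterion, or None if the record passes."""
    if not _is_damaging(record):
        return "not_damaging"
    if not record.vqsr_pass:
        return "vqsr"
    if record.gnomad_maf > cfg.maf_max:
        return "maf"
    calls = record.samples.values()
    if min(c.dp for c in calls) < cfg.dp_min:
        return "dp"
    if min(c.gq for c in calls) < cfg.gq_min:
        return "gq"
    if min(c.mq for c in calls) < cfg.mq_min:
        return "mq"
    if any(c.dp == 0 or c.pl_diff / c.dp < cfg.pldiff_dp_min for c in calls):
        return "pldiff_dp"
    if record.lcr:
        return "lcr"
    if cfg.require_homozygous_or_comphet and record.genotype != "hom":
        return "zygosity"
    return None


def quality_filter(
    records: Iterable[VariantRecord], cfg: FilterConfig | None = None
) -> tuple[list[VariantRecord], Counter]:
    """Stage-one quality filter.

    Returns surviving records and a tally of the first failing criterion
    per rejected record (keys: not_damaging, vqsr, maf, dp, gq, mq,
    pldiff_dp, lcr, and zygosity under the recessive preset).
    """
    cfg = cfg or FilterConfig()
    kept: list[VariantRecord] = []
    tally: Counter = Counter()
    for rec in records:
        failure = _quality_failure(rec, cfg)
        if failure is None:
            kept.append(rec)
        else:
            tally[failure] += 1
    return kept, tally


def _persistence_failure(record: VariantRecord, cfg: FilterConfig) -> str | None:
    """First failing persistence criterion, or None if the record passes."""
    if len(record.present_in_rol) != cfg.rol_required:
        raise ValueError(
            f"{record.variant_id}: expected {cfg.rol_required} late-replicate "
            f"presence flags, got {len(record.present_in_rol)}"
        )
    for key in (CONTROL, RESISTANT):
        if key not in record.samples:
            raise ValueError(f"{record.variant_id}: missing paired sample {key!r}")
    c = record.samples[CONTROL]
    r = record.samples[RESISTANT]
    if c.dp <= cfg.dp_paired_excl:
        return "dp_control"
    if r.dp <= cfg.dp_paired_excl:
        return "dp_resistant"
    if r.alt_reads <= cfg.alt_r_excl:
        return "alt_resistant"
    if c.ref_reads <= cfg.ref_c_excl:
        return "ref_control"
    nraf_r = nraf(record, RESISTANT)
    if nraf_r <= cfg.nraf_r_excl:
        return "nraf_resistant"
    if nraf_r - nraf(record, CONTROL) <= cfg.delta_nraf_excl:
        return "delta_nraf"
    if not all(record.present_in_rol):
        return "rol"
    return None


def persistence_filter(
    records: Iterable[VariantRecord], cfg: FilterConfig | None = None
) -> list[VariantRecord]:
    """Stage-two paired control-vs-resistant persistence filter.

    Every threshold here is strict: depth must exceed 11 in both paired
    samples, alt support in the resistant and ref support in the control
    must exceed 2 reads, resistant NRAF must exceed 0.15, the NRAF shift
    must exceed 0.25, and the variant must be present in all late
    in-vivo replicates.
    """
    cfg = cfg or FilterConfig()
    return [rec for rec in records if _persistence_failure(rec, cfg) is None]


def expression_filter(
    records: Iterable[VariantRecord],
    rpkm_table: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> list[VariantRecord]:
    """Keep variants in genes with mean RPKM strictly above the gate.

    ``rpkm_table`` is gene x sample; the mean is taken across all its
    samples.  A record whose gene is absent from the table is an error.
    """
    cfg = cfg or FilterConfig()
    means = rpkm_table.mean(axis=1)
    kept = []
    for rec in records:
        if rec.gene not in means.index:
            raise KeyError(f"gene {rec.gene!r} absent from RPKM table")
        if means[rec.gene] > cfg.rpkm_excl:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# TSV adapters: one row per variant, paired-sample fields suffixed _C2D/_R2D,
# late-replicate presence flags present_RoL1..present_RoL4.

_PAIR_SUFFIX = {CONTROL: "C2D", RESISTANT: "R2D"}
_CALL_FIELDS = ("dp", "alt_reads", "ref_reads", "gq", "mq", "pl_diff")


def records_to_table(records: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict = {
            "variant_id": rec.variant_id,
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            "alt": rec.alt,
            "gene": rec.gene,
            "consequence": rec.consequence,
            "metasvm_deleterious": rec.metasvm_deleterious,
            "vqsr_pass": rec.vqsr_pass,
            "gnomad_maf": rec.gnomad_maf,
            "lcr": rec.lcr,
            "genotype": rec.genotype,
        }
        for key, suffix in _PAIR_SUFFIX.items():
            call = rec.samples[key]
            for f in _CALL_FIELDS:
                row[f"{f}_{suffix}"] = getattr(call, f)
        for i, flag in enumerate(rec.present_in_rol, start=1):
            row[f"present_RoL{i}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_table(table: pd.DataFrame) -> list[VariantRecord]:
    records = []
    rol_cols = sorted(c for c in table.columns if c.startswith("present_RoL"))
    for _, row in table.iterrows():
        samples = {}
        for key, suffix in _PAIR_SUFFIX.items():
            samples[key] = SampleCall(
                dp=int(row[f"dp_{suffix}"]),
                alt_reads=int(row[f"alt_reads_{suffix}"]),
                ref_reads=int(row[f"ref_reads_{suffix}"]),
                gq=float(row[f"gq_{suffix}"]),
                mq=float(row[f"mq_{suffix}"]),
                pl_diff=float(row[f"pl_diff_{suffix}"]),
            )
        records.append(
            VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=str(row["gene"]),
                consequence=str(row["consequence"]),
                metasvm_deleterious=bool(row["metasvm_deleterious"]),
                vqsr_pass=bool(row["vqsr_pass"]),
                gnomad_maf=float(row["gnomad_maf"]),
                lcr=bool(row["lcr"]),
                samples=samples,
                present_in_rol=tuple(bool(row[c]) for c in rol_cols),
                genotype=str(row.get("genotype", "het")),
                variant_id=str(row.get("variant_id", "")),
            )
        )
    return records
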