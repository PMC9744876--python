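"""Cross-species contamination filtering for dual-species RNA-seq counts.

Bulk sequencing of intact xenograft tissue yields reads from both the
grafted (e.g. human tumor) and host (e.g. mouse stroma) transcriptomes.
A small fraction of reads from one species aligns uniquely to genes
annotated in the other species' genome.  Species-pure control libraries
are used to estimate, per gene, the propensity of opposite-species reads
to cross-map to it; genes whose predicted cross-mapped reads exceed a
fraction (default 10%) of their observed reads in xenograft samples are
excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

HUMAN = "human"
MOUSE = "mouse"
SPECIES = (HUMAN, MOUSE)

XENOGRAFT = "xenograft"
HUMAN_ONLY = "human_only"
MOUSE_ONLY = "mouse_only"
SAMPLE_CLASSES = (XENOGRAFT, HUMAN_ONLY, MOUSE_ONLY)

#: control class that is species-pure for the *opposite* species of a gene
_OPPOSITE_CONTROL = {HUMAN: MOUSE_ONLY, MOUSE: HUMAN_ONLY}
_OPPOSITE_SPECIES = {HUMAN: MOUSE, MOUSE: HUMAN}


@dataclass
class DualSpeciesCounts:
    """Gene x sample integer count matrix with species and class annotations.

    Parameters
    ----------
    counts
        Genes in rows, samples in columns, non-negative integers.
    gene_info
        Indexed by gene id; must carry a ``species`` column with values
        ``human``/``mouse``; a ``length_bp`` column is optional and only
        needed for RPKM downstream.
    sample_info
        Indexed by sample id; must carry a ``class`` column with values
        ``xenograft``/``human_only``/``mouse_only``.
    """

    counts: pd.DataFrame
    gene_info: pd.DataFrame
    sample_info: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(pd.Index(self.gene_info.index)):
            if set(self.counts.index) != set(self.gene_info.index):
                raise ValueError("counts rows and gene_info index disagree")
            self.gene_info = self.gene_info.loc[self.counts.index]
        if not self.counts.columns.equals(pd.Index(self.sample_info.index)):
            if set(self.counts.columns) != set(self.sample_info.index):
                raise ValueError("counts columns and sample_info index disagree")
            self.sample_info = self.sample_info.loc[self.counts.columns]
        bad_species = set(self.gene_info["species"]) - set(SPECIES)
        if bad_species:
            raise ValueError(f"unknown species labels: {sorted(bad_species)}")
        bad_classes = set(self.sample_info["class"]) - set(SAMPLE_CLASSES)
        if bad_classes:
            raise ValueError(f"unknown sample classes: {sorted(bad_classes)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def genes_of(self, species: str) -> pd.Index:
        return self.counts.index[self.gene_info["species"] == species]

    def samples_of(self, cls: str) -> pd.Index:
        return self.counts.columns[self.sample_info["class"] == cls]

    def species_total(self, sample: str, species: str) -> float:
        """Total reads mapped to genes annotated to ``species`` in ``sample``."""
        if sample not in self.counts.columns:
            raise KeyError(f"unknown sample id: {sample!r}")
        return float(self.counts.loc[self.genes_of(species), sample].sum())


@dataclass
class CrossMapModel:
    """Fitted per-gene cross-mapping propensities.

    ``rate[g]`` is the expected number of reads cross-mapped to gene ``g``
    per read mapped to the opposite species' genes, estimated from
    species-pure controls.
    """

    rate: pd.Series
    control_totals: pd.DataFrame  # per control sample: class, species_total
    n_controls_used: dict = field(default_factory=dict)


def estimate_crossmap_rates(
    data: DualSpeciesCounts,
    pooling: Literal["pooled", "mean_of_ratios"] = "pooled",
) -> CrossMapModel:
    """Estimate per-gene cross-mapping rates from species-pure controls.

    For a human gene the rate is the ratio of its total reads in
    mouse-only controls to those controls' total reads on mouse genes
    (pooled across controls by default, or the per-sample mean of ratios
    with ``pooling="mean_of_ratios"``); symmetric for mouse genes over
    human-only controls.

    Raises
    ------
    ValueError
        If either control class is absent, or a control library has zero
        reads on its own species' genes.
    """
    for cls in (HUMAN_ONLY, MOUSE_ONLY):
        if len(data.samples_of(cls)) == 0:
            raise ValueError(f"no samples of required control class {cls!r}")

    rate = pd.Series(0.0, index=data.counts.index)
    rows = []
    n_used: dict[str, int] = {}
    for species in SPECIES:
        ctrl_cls = _OPPOSITE_CONTROL[species]  # pure libraries of the other species
        ctrl_species = _OPPOSITE_SPECIES[species]
        ctrl_samples = data.samples_of(ctrl_cls)
        n_used[species] = len(ctrl_samples)
        totals = np.array([data.species_total(s, ctrl_species) for s in ctrl_samples])
        if (totals <= 0).any():
            bad = ctrl_samples[totals <= 0].tolist()
            raise ValueError(f"zero {ctrl_species}-gene library total in controls {bad}")
        genes = data.genes_of(species)
        sub = data.counts.loc[genes, ctrl_samples]
        if pooling == "pooled":
            rate.loc[genes] = sub.sum(axis=1) / totals.sum()
        elif pooling == "mean_of_ratios":
            rate.loc[genes] = (sub / totals).mean(axis=1)
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
        for s, t in zip(ctrl_samples, totals):
            rows.append({"sample_id": s, "class": ctrl_cls, "species_total": t})

    control_totals = pd.DataFrame(rows).set_index("sample_id")
    return CrossMapModel(rate=rate, control_totals=control_totals, n_controls_used=n_used)


def predict_crossmapped_reads(
    model: CrossMapModel, data: DualSpeciesCounts, sample: str
) -> pd.Series:
    """Predicted cross-mapped read count per gene in one xenograft sample.

    For a human gene: rate x (sample's total reads on mouse genes);
    symmetric for mouse genes.
    """
    if sample not in data.counts.columns:
        raise KeyError(f"unknown sample id: {sample!r}")
    pred = pd.Series(0.0, index=data.counts.index)
    for species in SPECIES:
        genes = data.genes_of(species)
        opp_total = data.species_total(sample, _OPPOSITE_SPECIES[species])
        pred.loc[genes] = model.rate.loc[genes] * opp_total
    return pred


@dataclass
class FilterReport:
    """Gene partition produced by :func:`filter_genes` plus the per-gene report."""

    retained: pd.Index
    excluded: pd.Index
    report: pd.DataFrame  # gene_id index: species, rate, mean_pred_fraction, decision, reason


def filter_genes(
    model: CrossMapModel,
    data: DualSpeciesCounts,
    threshold: float = 0.10,
    aggregate: Literal["mean", "max"] = "mean",
) -> FilterReport:
    """Partition genes into retained / excluded by predicted contamination.

    A gene is excluded iff the mean (or max) over xenograft samples of
    ``predicted cross-mapped reads / observed reads`` strictly exceeds
    ``threshold``.  An observed count of 0 with a positive prediction
    contributes fraction 1.0; 0/0 contributes 0.  Genes with zero
    observed reads in every xenograft sample are excluded with reason
    ``no_signal``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if not model.rate.index.equals(data.counts.index):
        raise ValueError("model fitted on a different gene index")
    xeno = data.samples_of(XENOGRAFT)
    if len(xeno) == 0:
        raise ValueError("no xenograft samples to filter on")

    fractions = pd.DataFrame(index=data.counts.index, columns=xeno, dtype=float)
    for s in xeno:
        pred = predict_crossmapped_reads(model, data, s)
        obs = data.counts[s].astype(float)
        frac = pred / obs
        frac[(obs == 0) & (pred > 0)] = 1.0
        frac[(obs == 0) & (pred == 0)] = 0.0
        fractions[s] = frac

    agg = fractions.mean(axis=1) if aggregate == "mean" else fractions.max(axis=1)
    if aggregate not in ("mean", "max"):
        raise ValueError(f"unknown aggregate {aggregate!r}")

    no_signal = (data.counts[xeno].sum(axis=1) == 0)
    contaminated = agg > threshold  # strict: fraction exactly at threshold is retained
    excluded_mask = contaminated | no_signal

    reason = pd.Series("", index=data.counts.index, dtype=object)
    reason[contaminated] = "crossmap"
    reason[no_signal] = "no_signal"

    report = pd.DataFrame(
        {
            "species": data.gene_info["species"],
            "rate": model.rate,
            "mean_pred_fraction": agg,
            "decision": np.where(excluded_mask, "excluded", "retained"),
            "reason": reason,
        }
    )
    return FilterReport(
        retained=data.counts.index[~excluded_mask],
        excluded=data.counts.index[excluded_mask],
        report=report,
    )
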