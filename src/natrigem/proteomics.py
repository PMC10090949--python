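"""Spectral-count proteomics: normalization, model-expression coverage,
one-way ANOVA differential expression, and category weight fractions.

Spectral counts are semi-quantitative: the number of peptide-spectrum
matches attributed to a protein in one MS run. Scaffold-style
normalization rescales each sample so its total matches the mean of the
raw sample totals, preserving within-sample rank order and the grand
total. Differential expression between salinity groups uses the classical
one-way ANOVA F test without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gpr import GeneRule
from .model import MetabolicModel


@dataclass
class ProteomeTable:
    """samples x proteins spectral-count matrix with metadata.

    ``counts``: DataFrame indexed by sample id, columns protein ids.
    ``sample_meta``: per-sample metadata (salinity_mM, growth_phase,
    replicate). ``protein_meta``: per-protein metadata (length_aa,
    mass_g_per_mmol, category).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    protein_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative spectral counts")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.columns)

    def detected_proteins(self, min_count: float = 1.0) -> set[str]:
        """Proteins identified in at least one sample."""
        mask = (self.counts >= min_count).any(axis=0)
        return set(self.counts.columns[mask])


def normalize_counts(table: ProteomeTable) -> ProteomeTable:
    """Scale each sample so its total equals the mean raw sample total."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total counts")
    factors = totals.mean() / totals
    return ProteomeTable(counts=table.counts.mul(factors, axis=0),
                         sample_meta=table.sample_meta,
                         protein_meta=table.protein_meta)


@dataclass
class CoverageReport:
    n_active_reactions: int
    n_gene_associated: int
    n_fully_detected: int
    n_all_but_one: int

    @property
    def fraction_fully_detected(self) -> float:
        return self.n_fully_detected / self.n_gene_associated

    @property
    def fraction_all_but_one(self) -> float:
        return self.n_all_but_one / self.n_gene_associated


def _rule_detection(rule: GeneRule, detected: set[str]) -> tuple[bool, bool]:
    """(fully detected, all-but-one) via minimal satisfying gene sets.

    "Entirely found" is read permissively: any one complete
    isoenzyme/complex (a minimal satisfying set of the rule) within the
    detected set suffices.
    """
    best_missing = min(len(s - detected) for s in rule.minimal_gene_sets())
    return best_missing == 0, best_missing <= 1


def reaction_expression_coverage(model: MetabolicModel, active: set[str],
                                 detected: set[str]) -> CoverageReport:
    """How much of the active (flux-carrying) network is seen in proteomics."""
    unknown = active - set(model.reaction_ids)
    if unknown:
        raise ValueError(f"active set contains unknown reactions {sorted(unknown)}")
    n_full = n_abo = n_assoc = 0
    for rid in active:
        rule = model.reaction(rid).gene_rule
        if rule.is_empty:
            continue
        n_assoc += 1
        full, abo = _rule_detection(rule, detected)
        n_full += full
        n_abo += abo
    return CoverageReport(n_active_reactions=len(active),
                          n_gene_associated=n_assoc,
                          n_fully_detected=n_full, n_all_but_one=n_abo)


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA F and p over >= 2 groups.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom. No
    multiple-testing correction is applied here; callers screening many
    proteins receive the raw per-protein p values.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    grand = np.concatenate(arrays).mean()
    between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    if within == 0:
        if between == 0:
            return 0.0, 1.0
        raise ValueError("zero within-group variance: F undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def differential_expression(table: ProteomeTable, group_column: str,
                            group_a, group_b) -> pd.DataFrame:
    """Per-protein ANOVA between two sample groups (e.g. salinities)."""
    meta = table.sample_meta
    ids_a = meta.index[meta[group_column] == group_a]
    ids_b = meta.index[meta[group_column] == group_b]
    rows = []
    for prot in table.proteins:
        try:
            f, p = one_way_anova([table.counts.loc[ids_a, prot],
                                  table.counts.loc[ids_b, prot]])
        except ValueError:
            f, p = np.nan, np.nan
        rows.append({"protein": prot, "F": f, "p": p})
    return pd.DataFrame(rows).set_index("protein")


def category_weight_fraction(table: ProteomeTable, sample: str, category: str,
                             mass_weighted: bool = True) -> float:
    """Percent of a sample's proteome weight in one category.

    With ``mass_weighted`` (default) each protein contributes
    count x molecular mass — raw counts are length-biased, and a *weight*
    fraction implies mass weighting; the count-only variant is kept for
    sensitivity analysis.
    """
    if sample not in table.counts.index:
        raise KeyError(f"unknown sample {sample!r}")
    cats = table.protein_meta["category"]
    members = [p for p in table.proteins if cats.get(p) == category]
    if not members:
        raise ValueError(f"no protein in category {category!r}")
    counts = table.counts.loc[sample]
    if mass_weighted:
        mass = table.protein_meta["mass_g_per_mmol"]
        weights = counts * mass.reindex(counts.index)
    else:
        weights = counts
    return float(weights[members].sum() / weights.sum() * 100.0)
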