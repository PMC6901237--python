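"""Cohort-wide mutation recurrence and its chance-level null.

A mutation is *recurrent* when the identical event — same contig, position,
reference and alternate allele — is carried by at least ``min_samples``
(default 2) samples of a scope.  Scopes can be the whole cohort
("pan-cancer"), a tumour type, or a cluster.  The Monte-Carlo null places
each sample's mutation count uniformly over a single genome of given size and
measures how much recurrence arises from such collisions alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

KEY_COLUMNS = ["chrom", "pos", "ref", "alt", "kind"]


@dataclass(frozen=True)
class MutationKey:
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str


@dataclass
class RecurrenceIndex:
    """Carrier counts per distinct mutation within one scope.

    ``keys`` has one row per distinct mutation with its subtype, 1 bp flag
    and ``n_carriers``; ``pairs`` holds the deduplicated (sample, mutation)
    incidence used for carrier lookups.
    """

    scope_label: str
    keys: pd.DataFrame
    pairs: pd.DataFrame
    min_samples: int = 2

    def is_recurrent(self, key: MutationKey) -> bool:
        m = self.keys
        sel = (
            (m["chrom"] == key.chrom) & (m["pos"] == key.pos)
            & (m["ref"] == key.ref) & (m["alt"] == key.alt) & (m["kind"] == key.kind)
        )
        hit = m.loc[sel, "n_carriers"]
        return bool(len(hit)) and int(hit.iloc[0]) >= self.min_samples

    def carriers_of(self, key: MutationKey) -> frozenset[str]:
        p = self.pairs
        sel = (
            (p["chrom"] == key.chrom) & (p["pos"] == key.pos)
            & (p["ref"] == key.ref) & (p["alt"] == key.alt) & (p["kind"] == key.kind)
        )
        return frozenset(p.loc[sel, "sample_id"])

    @property
    def carriers(self) -> dict[MutationKey, frozenset[str]]:
        """Full carrier map (materialized on demand; meant for small cohorts)."""
        out: dict[MutationKey, frozenset[str]] = {}
        for key_vals, grp in self.pairs.groupby(KEY_COLUMNS, sort=False):
            out[MutationKey(*key_vals)] = frozenset(grp["sample_id"])
        return out


def build_index(
    mutations: pd.DataFrame,
    grouping: Optional[Mapping[str, str]] = None,
    min_samples: int = 2,
) -> dict[str, RecurrenceIndex]:
    """Build one RecurrenceIndex per scope from a normalized mutation table.

    ``grouping`` maps sample_id to a scope label; ``None`` yields a single
    pan-cancer index.  Duplicate (sample, mutation) pairs are collapsed with
    a warning.
    """
    df = mutations
    if grouping is None:
        scopes = {"pan-cancer": df}
    else:
        labels = df["sample_id"].map(dict(grouping))
        scopes = {str(lab): sub for lab, sub in df.groupby(labels, sort=False)}
    out = {}
    for label, sub in scopes.items():
        pairs = sub[["sample_id"] + KEY_COLUMNS + ["subtype", "is_1bp"]]
        dedup = pairs.drop_duplicates(subset=["sample_id"] + KEY_COLUMNS)
        if len(dedup) < len(pairs):
            log.warning("%s: collapsed %d duplicate (sample, mutation) pairs",
                        label, len(pairs) - len(dedup))
        keys = (
            dedup.groupby(KEY_COLUMNS, sort=False)
            .agg(n_carriers=("sample_id", "size"), subtype=("subtype", "first"),
                 is_1bp=("is_1bp", "first"))
            .reset_index()
        )
        out[label] = RecurrenceIndex(label, keys, dedup, min_samples)
    return out


def build_pancancer_index(mutations: pd.DataFrame, min_samples: int = 2) -> RecurrenceIndex:
    return build_index(mutations, None, min_samples)["pan-cancer"]


@dataclass
class ClassSummary:
    n_distinct: int
    n_recurrent_distinct: int

    @property
    def pct_recurrent(self) -> float:
        return 100.0 * self.n_recurrent_distinct / self.n_distinct if self.n_distinct else 0.0


@dataclass
class RecurrenceSummary:
    """Distinct-mutation recurrence counts for one scope.

    Every distinct mutation is counted once regardless of how many samples
    carry it; SSMs and SIMs are summarized separately, with per-subtype
    breakdowns (1 bp subtypes for SIMs).
    """

    scope_label: str
    ssm: ClassSummary
    sim: ClassSummary
    by_ssm_subtype: dict[str, ClassSummary] = field(default_factory=dict)
    by_sim_subtype: dict[str, ClassSummary] = field(default_factory=dict)


def summarize(index: RecurrenceIndex) -> RecurrenceSummary:
    keys = index.keys
    rec = keys["n_carriers"] >= index.min_samples

    def _cls(mask) -> ClassSummary:
        return ClassSummary(int(mask.sum()), int((mask & rec).sum()))

    by_ssm = {}
    for st, grp in keys[keys["kind"] == "SSM"].groupby("subtype", sort=False):
        by_ssm[st] = ClassSummary(len(grp), int((grp["n_carriers"] >= index.min_samples).sum()))
    by_sim = {}
    sim1 = keys[(keys["kind"] == "SIM") & keys["is_1bp"]]
    for st, grp in sim1.groupby("subtype", sort=False):
        by_sim[st] = ClassSummary(len(grp), int((grp["n_carriers"] >= index.min_samples).sum()))
    return RecurrenceSummary(
        index.scope_label,
        _cls(keys["kind"] == "SSM"),
        _cls(keys["kind"] == "SIM"),
        by_ssm,
        by_sim,
    )


def annotate_recurrence(mutations: pd.DataFrame, index: RecurrenceIndex) -> pd.DataFrame:
    """Return the table with a boolean ``recurrent`` column from the index.

    A sample's own carriage counts toward the carrier total, so with the
    default threshold a mutation is recurrent when at least one *other*
    sample in the index's scope carries it too.
    """
    merged = mutations.merge(
        index.keys[KEY_COLUMNS + ["n_carriers"]], on=KEY_COLUMNS, how="left"
    )
    merged["recurrent"] = merged["n_carriers"].fillna(0) >= index.min_samples
    return merged.drop(columns="n_carriers")


def per_sample_recurrence(
    sample_id: str, mutations: pd.DataFrame, index: RecurrenceIndex
) -> dict[str, float]:
    """Recurrence fractions of one sample against a cohort index.

    Returns overall recurrent-SSM and recurrent-SIM percentages (denominator:
    the sample's own SSM / SIM counts), the percentage of the sample's
    recurrent mutations that are SIMs, and per-subtype recurrent percentages
    (six SSM subtypes; four 1 bp SIM subtypes, denominator the sample's count
    of that subtype).  Empty denominators yield 0.
    """
    sample = mutations[mutations["sample_id"] == sample_id]
    ann = annotate_recurrence(sample, index)

    def _pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    is_ssm = ann["kind"] == "SSM"
    is_sim = ann["kind"] == "SIM"
    rec = ann["recurrent"]
    out = {
        "pct_recurrent_ssm": _pct(int((is_ssm & rec).sum()), int(is_ssm.sum())),
        "pct_recurrent_sim": _pct(int((is_sim & rec).sum()), int(is_sim.sum())),
        "pct_recurrent_that_are_sim": _pct(int((is_sim & rec).sum()), int(rec.sum())),
    }
    from .io_context import SIM_SUBTYPES, SSM_SUBTYPES

    for st in SSM_SUBTYPES:
        m = is_ssm & (ann["subtype"] == st)
        out[f"pct_recurrent_ssm[{st}]"] = _pct(int((m & rec).sum()), int(m.sum()))
    for st in SIM_SUBTYPES:
        m = is_sim & ann["is_1bp"] & (ann["subtype"] == st)
        out[f"pct_recurrent_sim[{st}]"] = _pct(int((m & rec).sum()), int(m.sum()))
    return out


@dataclass
class ChanceRecurrenceEstimate:
    """Monte-Carlo estimate of recurrence arising from positional chance alone."""

    n_sims: int
    genome_size: int
    per_sample_counts: np.ndarray
    expected_pct_recurrent: float
    sim_distribution: np.ndarray
    seed: int
    observed_pct_recurrent: Optional[float] = None
    sim_n_distinct: Optional[np.ndarray] = None
    sim_n_recurrent: Optional[np.ndarray] = None

    @property
    def observed_over_expected(self) -> Optional[float]:
        if self.observed_pct_recurrent is None or self.expected_pct_recurrent == 0:
            return None
        return self.observed_pct_recurrent / self.expected_pct_recurrent


def _sample_distinct(rng: np.random.Generator, genome_size: int, count: int) -> np.ndarray:
    """``count`` distinct uniform positions in [0, genome_size)."""
    if count > genome_size:
        raise ValueError(f"count {count} exceeds genome size {genome_size}")
    if count * 5 >= genome_size:
        return rng.permutation(genome_size)[:count]
    # Sparse regime: draw with replacement and top up until distinct.
    chosen = np.unique(rng.integers(0, genome_size, size=count))
    while len(chosen) < count:
        extra = rng.integers(0, genome_size, size=count - len(chosen))
        chosen = np.unique(np.concatenate([chosen, extra]))
    return chosen[:count] if len(chosen) > count else chosen


def simulate_chance_recurrence(
    per_sample_counts,
    genome_size: int,
    n_sims: int = 5000,
    seed: int = 0,
    observed_pct_recurrent: Optional[float] = None,
) -> ChanceRecurrenceEstimate:
    """Simulate recurrence under uniform, independent mutation placement.

    Each simulation draws, for every sample independently, its mutation count
    as distinct uniform positions over a genome of ``genome_size`` bp.  A
    position is recurrent when drawn by two or more samples, and the per-sim
    recurrence percentage is 100 x (distinct positions drawn by >=2 samples) /
    (distinct positions drawn at all).  The default of 5,000 simulations gives
    a stable mean at the cohort scales this package targets.
    """
    counts = np.asarray(per_sample_counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative mutation count")
    if counts.size and counts.max() > genome_size:
        raise ValueError("a sample's count exceeds the genome size")
    rng = np.random.default_rng(seed)
    pcts = np.empty(n_sims)
    n_distinct = np.zeros(n_sims, dtype=np.int64)
    n_recurrent = np.zeros(n_sims, dtype=np.int64)
    active = counts[counts > 0]
    sparse = active.size > 0 and int(active.max()) * 5 < genome_size
    offsets = np.arange(active.size, dtype=np.int64) * genome_size
    for s in range(n_sims):
        if active.size == 0:
            pcts[s] = 0.0
            continue
        if sparse:
            # One vectorized draw for every sample; within-sample duplicates
            # (rare in this regime) are rejected and redrawn, so each sample
            # is still uniform without replacement.
            codes = np.repeat(offsets, active) + rng.integers(
                0, genome_size, size=int(active.sum())
            )
            while True:
                codes.sort()
                codes = codes[np.concatenate([[True], codes[1:] != codes[:-1]])]
                short = active - np.bincount(codes // genome_size,
                                             minlength=active.size)
                if not short.any():
                    break
                extra = np.repeat(offsets, short) + rng.integers(
                    0, genome_size, size=int(short.sum())
                )
                codes = np.concatenate([codes, extra])
            draws = codes % genome_size
        else:
            draws = np.concatenate(
                [_sample_distinct(rng, genome_size, int(c)) for c in active]
            )
        draws.sort()
        boundary = np.flatnonzero(
            np.concatenate([[True], draws[1:] != draws[:-1]])
        )
        mult = np.diff(np.append(boundary, draws.size))
        n_distinct[s] = mult.size
        n_recurrent[s] = (mult >= 2).sum()
        pcts[s] = 100.0 * n_recurrent[s] / n_distinct[s]
    return ChanceRecurrenceEstimate(
        n_sims=n_sims,
        genome_size=genome_size,
        per_sample_counts=counts,
        expected_pct_recurrent=float(pcts.mean()),
        sim_distribution=pcts,
        seed=seed,
        observed_pct_recurrent=observed_pct_recurrent,
        sim_n_distinct=n_distinct,
        sim_n_recurrent=n_recurrent,
    )
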