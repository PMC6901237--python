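"""Sequence-context motifs around recurrent mutations.

For a stratum of SSMs (one subtype within one cluster), the +/-10 bp contexts
are read on the strand where the mutated base is the pyrimidine, split into
recurrent and non-recurrent sets (each recurrent mutation contributing one
context), and summarized position-by-position with the relative entropy

    RE_i = sum_b f(b_i) log2(f(b_i) / P(b))

against genome base priors P.  Positions with RE_i >= 0.25 define the
enriched motif; its genome-wide background fraction is estimated by counting
non-overlapping k-mers on both strands; and enrichment of the motif among
recurrent versus non-recurrent contexts is tested with a chi-squared test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genome import Genome, revcomp
from .stats import chi2_2x2

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
IUPAC_SETS = {v: set(k) for k, v in IUPAC.items()}


@dataclass
class BasePrior:
    """Genome base probabilities, strand-symmetrized (P(A)=P(T), P(C)=P(G))."""

    p: dict[str, float]

    def __post_init__(self):
        total = sum(self.p.values())
        if abs(total - 1.0) > 1e-9 or any(v <= 0 for v in self.p.values()):
            raise ValueError("prior must be strictly positive and sum to 1")

    @classmethod
    def uniform(cls) -> "BasePrior":
        return cls({b: 0.25 for b in BASES})

    @classmethod
    def from_genome(cls, genome: Genome) -> "BasePrior":
        counts = {b: 0 for b in BASES}
        for chrom in genome.contigs:
            seq = genome.sequence(chrom)
            for b in BASES:
                counts[b] += seq.count(b)
        at = counts["A"] + counts["T"]
        cg = counts["C"] + counts["G"]
        total = at + cg
        if total == 0:
            raise ValueError("genome contains no ACGT bases")
        return cls({"A": at / (2 * total), "T": at / (2 * total),
                    "C": cg / (2 * total), "G": cg / (2 * total)})


@dataclass
class ContextMatrix:
    """Positional base counts of mutation contexts (position 0 = mutated base)."""

    positions: np.ndarray  # e.g. -10..+10
    counts: np.ndarray  # len(positions) x 4, column order ACGT
    n_sequences: int
    sequences: list[str]  # the raw context strings, one per included mutation

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    @classmethod
    def from_sequences(cls, sequences: list[str], flank: int) -> "ContextMatrix":
        if not sequences:
            raise ValueError("empty context set")
        width = 2 * flank + 1
        counts = np.zeros((width, 4), dtype=np.int64)
        for seq in sequences:
            if len(seq) != width:
                raise ValueError(f"context of length {len(seq)}, expected {width}")
            for i, b in enumerate(seq):
                counts[i, _BASE_IDX[b]] += 1
        return cls(np.arange(-flank, flank + 1), counts, len(sequences), list(sequences))


def extract_contexts(
    stratum: pd.DataFrame,
    genome: Genome,
    flank: int = 10,
) -> tuple[Optional[ContextMatrix], Optional[ContextMatrix]]:
    """Pyrimidine-strand contexts of a recurrence-annotated SSM stratum.

    ``stratum`` is a slice of the normalized table (single subtype, single
    scope) carrying a boolean ``recurrent`` column from the scope's own
    index.  Contexts of complemented mutations are reverse-complemented so
    the mutated base is always the pyrimidine.  Recurrent mutations are
    deduplicated to one context each; mutations within ``flank`` bp of a
    contig end are excluded with a logged count.  Returns (recurrent,
    non-recurrent) matrices, either ``None`` when its set is empty.
    """
    if stratum.empty:
        raise ValueError("empty stratum")
    if "recurrent" not in stratum:
        raise ValueError("stratum must carry a 'recurrent' annotation")
    rec_seqs: list[str] = []
    nonrec_seqs: list[str] = []
    seen_keys = set()
    n_edge = 0
    for row in stratum.itertuples():
        if row.recurrent:
            key = (row.chrom, row.pos, row.ref, row.alt)
            if key in seen_keys:
                continue
            seen_keys.add(key)
        if row.pos - flank < 1 or row.pos + flank > genome.length(row.chrom):
            n_edge += 1
            continue
        seq = genome.fetch(row.chrom, row.pos - flank, row.pos + flank)
        if row.was_complemented:
            seq = revcomp(seq)
        (rec_seqs if row.recurrent else nonrec_seqs).append(seq)
    if n_edge:
        log.warning("excluded %d mutations within %d bp of a contig end", n_edge, flank)
    rec = ContextMatrix.from_sequences(rec_seqs, flank) if rec_seqs else None
    nonrec = ContextMatrix.from_sequences(nonrec_seqs, flank) if nonrec_seqs else None
    return rec, nonrec


@dataclass
class EntropyProfile:
    """Per-position relative entropy and signed per-base contributions."""

    positions: np.ndarray
    re: np.ndarray  # RE_i per position
    contributions: np.ndarray  # positions x 4, f * log2(f / P); sign marks
    # enrichment (+) or depletion (-) relative to the prior


def relative_entropy(matrix: ContextMatrix, prior: BasePrior) -> EntropyProfile:
    """RE_i = sum_b f(b_i) log2(f(b_i)/P(b)), with 0 log 0 treated as 0."""
    p = np.array([prior.p[b] for b in BASES])
    f = matrix.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(f > 0, f * np.log2(f / p), 0.0)
    return EntropyProfile(matrix.positions, contrib.sum(axis=1), contrib)


@dataclass
class MotifCall:
    """An enriched motif called from an entropy profile.

    ``motif`` is the IUPAC string over the reported window, ``mutation_offset``
    the index of the mutated base within it, and ``positions`` the
    corresponding context-relative positions.  ``bridged`` flags that
    non-passing positions inside the span were rendered as N (only possible
    when ``ungapped`` is off).
    """

    motif: str
    mutation_offset: int
    positions: np.ndarray
    passing_positions: tuple[int, ...]
    threshold: float
    ungapped: bool
    bridged: bool

    @property
    def display(self) -> str:
        """Motif with the mutated base bracketed, e.g. TT[C]TTT."""
        i = self.mutation_offset
        return f"{self.motif[:i]}[{self.motif[i]}]{self.motif[i + 1:]}"


def call_motif(
    profile: EntropyProfile,
    matrix: ContextMatrix,
    threshold: float = 0.25,
    ungapped: bool = False,
    representation_cutoff: float = 0.25,
) -> MotifCall:
    """Call the enriched motif: positions with RE >= threshold around the site.

    The mutated position is always reported.  With ``ungapped`` only the
    maximal contiguous run of passing positions containing the mutated site
    is kept; otherwise the full span is reported with non-passing interior
    positions bridged as N.  Each passing position is rendered as the IUPAC
    code of the bases whose contribution is positive and whose frequency
    reaches ``representation_cutoff`` (jointly enriched bases yield
    degenerate letters such as W).
    """
    pos = profile.positions
    passing = set(pos[profile.re >= threshold])
    passing.add(0)
    if len(passing) == 1:
        log.warning("no flank position passes RE >= %.2f; motif is the mutated base only",
                    threshold)
    if ungapped:
        kept = {0}
        p = 0
        while p + 1 in passing:
            p += 1
            kept.add(p)
        p = 0
        while p - 1 in passing:
            p -= 1
            kept.add(p)
        passing = kept
    span = np.arange(min(passing), max(passing) + 1)
    freqs = matrix.frequencies
    pos_index = {p: i for i, p in enumerate(pos)}
    letters = []
    bridged = False
    for p in span:
        if p not in passing:
            letters.append("N")
            bridged = True
            continue
        i = pos_index[p]
        enriched = {
            BASES[j]
            for j in range(4)
            if profile.contributions[i, j] > 0 and freqs[i, j] >= representation_cutoff
        }
        if not enriched:
            enriched = {BASES[int(np.argmax(freqs[i]))]}
        letters.append(IUPAC[frozenset(enriched)])
    return MotifCall(
        motif="".join(letters),
        mutation_offset=int(np.flatnonzero(span == 0)[0]),
        positions=span,
        passing_positions=tuple(sorted(passing)),
        threshold=threshold,
        ungapped=ungapped,
        bridged=bridged,
    )


@dataclass
class KmerBackground:
    k: int
    n_matching: int
    n_total: int
    n_constrained: int
    n_matching_constrained: int

    @property
    def pct_of_all_kmers(self) -> float:
        return 100.0 * self.n_matching / self.n_total if self.n_total else 0.0

    @property
    def pct_of_constrained_kmers(self) -> float:
        return 100.0 * self.n_matching_constrained / self.n_constrained if self.n_constrained else 0.0


def _window_matrix(seq: str, k: int) -> np.ndarray:
    """Non-overlapping k-windows of a sequence as a (n, k) byte matrix."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = len(arr) // k
    return arr[: n * k].reshape(n, k)


def genome_kmer_fraction(
    genome: Genome, motif: str, mutation_offset: int, shift: Optional[int] = None
) -> KmerBackground:
    """Fraction of genome k-mers matching an IUPAC motif.

    Windows of length k are taken with a shift of k (non-overlapping) across
    every contig and, added to that, across each contig's reverse complement —
    mirroring the strand collapsing of the mutation subtypes.  Windows with
    non-ACGT characters are discarded.  Reported both as a percentage of all
    k-mers and of the k-mers constrained to carry the motif's mutated base at
    ``mutation_offset``.  ``shift=1`` switches to overlapping windows.
    """
    k = len(motif)
    if shift is None:
        shift = k
    if not all(c in IUPAC_SETS for c in motif):
        raise ValueError(f"non-IUPAC motif {motif!r}")
    central = motif[mutation_offset]
    if central not in BASES:
        raise ValueError("the mutated base of the motif must be a concrete base")
    allowed = [np.frombuffer("".join(sorted(IUPAC_SETS[c])).encode(), dtype=np.uint8)
               for c in motif]
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    central_byte = ord(central)
    n_total = n_match = n_constr = n_match_constr = 0
    usable = False
    for chrom in genome.contigs:
        seq = genome.sequence(chrom)
        if len(seq) >= k:
            usable = True
        for strand_seq in (seq, revcomp(seq)):
            if shift == k:
                win = _window_matrix(strand_seq, k)
            else:
                arr = np.frombuffer(strand_seq.encode("ascii"), dtype=np.uint8)
                if len(arr) < k:
                    continue
                idx = np.arange(0, len(arr) - k + 1, shift)
                win = arr[idx[:, None] + np.arange(k)]
            if win.size == 0:
                continue
            valid = np.isin(win, acgt).all(axis=1)
            win = win[valid]
            match = np.ones(len(win), dtype=bool)
            for j in range(k):
                match &= np.isin(win[:, j], allowed[j])
            constrained = win[:, mutation_offset] == central_byte
            n_total += len(win)
            n_match += int(match.sum())
            n_constr += int(constrained.sum())
            n_match_constr += int((match & constrained).sum())
    if not usable:
        raise ValueError(f"motif length {k} exceeds every contig")
    return KmerBackground(k, n_match, n_total, n_constr, n_match_constr)


def sequence_has_motif(context: str, flank: int, call: MotifCall) -> bool:
    """Whether a context string matches the called motif at its positions."""
    for offset, letter in zip(call.positions, call.motif):
        base = context[flank + offset]
        if base not in IUPAC_SETS[letter]:
            return False
    return True


@dataclass
class EnrichmentResult:
    pct_recurrent_with_motif: float
    pct_nonrecurrent_with_motif: float
    table: np.ndarray  # rows: (recurrent, non-recurrent); cols: (motif, no motif)
    chi2: float
    p_value: float
    fisher_p: Optional[float] = None  # set when an expected cell count is < 5


def motif_enrichment_test(
    recurrent: ContextMatrix, non_recurrent: ContextMatrix, call: MotifCall
) -> EnrichmentResult:
    """Chi-squared test of motif presence in recurrent vs non-recurrent contexts."""
    flank = (len(recurrent.positions) - 1) // 2
    r_with = sum(sequence_has_motif(s, flank, call) for s in recurrent.sequences)
    n_with = sum(sequence_has_motif(s, flank, call) for s in non_recurrent.sequences)
    table = np.array([
        [r_with, recurrent.n_sequences - r_with],
        [n_with, non_recurrent.n_sequences - n_with],
    ])
    stat, p = chi2_2x2(table)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    fisher_p = None
    if (expected < 5).any():
        from scipy.stats import fisher_exact

        log.warning("expected cell count < 5; reporting Fisher exact fallback too")
        fisher_p = float(fisher_exact(table)[1])
    return EnrichmentResult(
        pct_recurrent_with_motif=100.0 * r_with / recurrent.n_sequences,
        pct_nonrecurrent_with_motif=100.0 * n_with / non_recurrent.n_sequences,
        table=table,
        chi2=stat,
        p_value=p,
        fisher_p=fisher_p,
    )


def plot_logo(profile: EntropyProfile, ax=None):
    """Sequence-logo-style plot: per-base bars of height f log2(f/P).

    Enriched bases stack above the axis, depleted below; the mutated
    position sits at x = 0.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    colors = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "T": "#e31a1c"}
    for i, pos in enumerate(profile.positions):
        up = down = 0.0
        order = np.argsort(-profile.contributions[i])
        for j in order:
            h = profile.contributions[i, j]
            base = BASES[j]
            if h >= 0:
                ax.bar(pos, h, bottom=up, color=colors[base], width=0.8)
                up += h
            else:
                ax.bar(pos, h, bottom=down, color=colors[base], width=0.8, alpha=0.6)
                down += h
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("position relative to mutated base")
    ax.set_ylabel("f · log2(f/P) (bits)")
    return ax
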