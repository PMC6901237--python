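"""Context extraction, relative entropy, motif calling, k-mer background."""

import numpy as np
import pandas as pd
import pytest

from recurmut.genome import Genome, revcomp
from recurmut.motifs import (
    BasePrior,
    ContextMatrix,
    call_motif,
    extract_contexts,
    genome_kmer_fraction,
    motif_enrichment_test,
    relative_entropy,
    sequence_has_motif,
)

from conftest import make_mutation_table


def contexts_from(seqs, flank=10):
    return ContextMatrix.from_sequences(seqs, flank)


def planted_contexts(rng, n, motif, offset, fraction, flank=10, center="C"):
    """Random flank-width contexts; a fraction carries ``motif`` with its
    mutated base (= ``center``) at position 0."""
    assert motif[offset] == center
    seqs = []
    for i in range(n):
        s = list(rng.choice(list("ACGT"), size=2 * flank + 1))
        s[flank] = center
        if i < int(fraction * n):
            for j, b in enumerate(motif):
                s[flank - offset + j] = b
        seqs.append("".join(s))
    return seqs


# ------------------------------------------------------------------ priors


def test_prior_from_genome_is_strand_symmetric():
    prior = BasePrior.from_genome(Genome({"c": "AACCGGTTGGCC"}))
    assert prior.p["A"] == prior.p["T"]
    assert prior.p["C"] == prior.p["G"]
    assert sum(prior.p.values()) == pytest.approx(1.0)


def test_prior_rejects_zero_entry():
    with pytest.raises(ValueError):
        BasePrior({"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.0})


# ------------------------------------------------------------ relative entropy


def test_relative_entropy_analytic_identities():
    uniform = BasePrior.uniform()
    m = contexts_from(["A", "C", "G", "T"], flank=0)
    prof = relative_entropy(m, uniform)
    assert abs(prof.re[0]) < 1e-12  # f = P -> RE = 0

    point = contexts_from(["A", "A", "A", "A"], flank=0)
    assert relative_entropy(point, uniform).re[0] == pytest.approx(2.0, abs=1e-12)

    half = contexts_from(["A", "A", "C", "C"], flank=0)
    assert relative_entropy(half, uniform).re[0] == pytest.approx(1.0, abs=1e-12)


def test_relative_entropy_invariant_under_joint_base_relabeling():
    prior = BasePrior({"A": 0.4, "C": 0.2, "G": 0.25, "T": 0.15})
    swapped = BasePrior({"A": 0.2, "C": 0.4, "G": 0.25, "T": 0.15})
    m1 = contexts_from(["A", "A", "C", "G"], flank=0)
    m2 = contexts_from(["C", "C", "A", "G"], flank=0)  # A<->C relabeled
    assert relative_entropy(m1, prior).re[0] == pytest.approx(
        relative_entropy(m2, swapped).re[0])


def test_relative_entropy_nonnegative():
    rng = np.random.default_rng(0)
    prior = BasePrior({"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3})
    for _ in range(50):
        seqs = ["".join(rng.choice(list("ACGT"), size=1)) for _ in range(30)]
        prof = relative_entropy(contexts_from(seqs, flank=0), prior)
        assert prof.re[0] >= -1e-12  # KL divergence


def test_contribution_signs_mark_enrichment_and_depletion():
    prior = BasePrior.uniform()
    m = contexts_from(["A"] * 9 + ["C"], flank=0)
    prof = relative_entropy(m, prior)
    assert prof.contributions[0, 0] > 0  # A enriched over 0.25
    assert prof.contributions[0, 1] < 0  # C at 0.1, depleted


# ---------------------------------------------------------------- motif calls


def test_call_motif_recovers_planted_6mer():
    rng = np.random.default_rng(1)
    seqs = planted_contexts(rng, 400, "TTCTTT", 2, fraction=0.8)
    m = contexts_from(seqs)
    call = call_motif(relative_entropy(m, BasePrior.uniform()), m)
    assert call.motif == "TTCTTT"
    assert call.mutation_offset == 2
    assert call.display == "TT[C]TTT"
    assert not call.bridged


def test_context_free_stratum_yields_single_base_motif():
    rng = np.random.default_rng(2)
    seqs = planted_contexts(rng, 400, "C", 0, fraction=1.0)  # center fixed only
    m = contexts_from(seqs)
    call = call_motif(relative_entropy(m, BasePrior.uniform()), m)
    assert call.motif == "C" and call.passing_positions == (0,)


def test_call_motif_emits_degenerate_letter_for_joint_enrichment():
    # A C>G-like stratum where the +1 position is A or T in equal shares
    rng = np.random.default_rng(3)
    seqs = []
    for i in range(400):
        s = list(rng.choice(list("ACGT"), size=21))
        s[9], s[10], s[11] = "T", "C", ("A" if i % 2 else "T")  # CTC[W]
        s[8] = "C"
        seqs.append("".join(s))
    m = contexts_from(seqs)
    call = call_motif(relative_entropy(m, BasePrior.uniform()), m)
    assert call.motif == "CTCW"
    assert call.mutation_offset == 2


def test_ungapped_motif_trims_to_contiguous_run():
    rng = np.random.default_rng(4)
    seqs = []
    for i in range(400):
        s = list(rng.choice(list("ACGT"), size=21))
        s[10] = "C"
        s[11] = "T"
        s[14] = "G"  # distal passing position separated by a gap
        seqs.append("".join(s))
    m = contexts_from(seqs)
    prof = relative_entropy(m, BasePrior.uniform())
    gapped = call_motif(prof, m, ungapped=False)
    assert gapped.bridged and "N" in gapped.motif
    ungapped = call_motif(prof, m, ungapped=True)
    assert ungapped.motif == "CT" and not ungapped.bridged


# ---------------------------------------------------------- context extraction


def stratum_table(entries):
    rows, flags = [], []
    for sample, pos, complemented, recurrent in entries:
        rows.append((sample, "c", pos, "C", "T", "SSM", "C>T"))
        flags.append((complemented, recurrent))
    table = make_mutation_table(rows)
    table["was_complemented"] = [f[0] for f in flags]
    table["recurrent"] = [f[1] for f in flags]
    return table


def test_extract_contexts_strand_and_dedup():
    seq = "A" * 10 + "C" + "G" * 10 + "C" + "T" * 10
    genome = Genome({"c": seq})
    table = stratum_table([
        ("s1", 11, False, True), ("s2", 11, False, True), ("s3", 11, False, True),
        ("s1", 22, True, False),
    ])
    rec, nonrec = extract_contexts(table, genome)
    assert rec.n_sequences == 1  # three carriers, one context
    assert rec.sequences[0] == seq[0:21]
    # complemented mutation: context is the reverse complement of the window
    assert nonrec.sequences[0] == revcomp(seq[11:32])


def test_extract_contexts_excludes_contig_edges():
    genome = Genome({"c": "ACGT" * 10})
    table = stratum_table([("s1", 2, False, False), ("s1", 20, False, False)])
    _, nonrec = extract_contexts(table, genome)
    assert nonrec.n_sequences == 1


def test_extract_contexts_rejects_empty_stratum():
    with pytest.raises(ValueError):
        extract_contexts(stratum_table([]).iloc[0:0], Genome({"c": "ACGT"}))


def test_dedup_invariant_to_carrier_multiplicity():
    seq = "ACGT" * 20
    genome = Genome({"c": seq})
    few = stratum_table([("s1", 30, False, True), ("s2", 30, False, True)])
    many = stratum_table([(f"s{i}", 30, False, True) for i in range(10)])
    rec_few, _ = extract_contexts(few, genome)
    rec_many, _ = extract_contexts(many, genome)
    assert np.array_equal(rec_few.counts, rec_many.counts)


# ------------------------------------------------------------- k-mer fractions


def test_kmer_fraction_toy_genome_brute_force():
    # forward windows of CTCT: {CT, CT}; reverse complement AGAG: {AG, AG}
    bg = genome_kmer_fraction(Genome({"c": "CTCT"}), "CT", 0)
    assert bg.n_total == 4 and bg.n_matching == 2
    assert bg.pct_of_all_kmers == pytest.approx(50.0)
    # constrained to C at offset 0: forward CT windows only
    assert bg.pct_of_constrained_kmers == pytest.approx(100.0)


def test_kmer_fraction_all_N_motif_matches_everything():
    bg = genome_kmer_fraction(Genome({"c": "ACGTACGTAC"}), "NCN", 1)
    assert bg.pct_of_all_kmers > 0
    assert bg.n_matching == sum(
        1 for w in _windows("ACGTACGTAC", 3) if w[1] == "C"
    ) + sum(1 for w in _windows(revcomp("ACGTACGTAC"), 3) if w[1] == "C")


def _windows(seq, k):
    return [seq[i : i + k] for i in range(0, len(seq) - k + 1, k)]


def test_kmer_fraction_single_base_recovers_prior():
    genome = Genome({"c": "AACCGGTTAACC"})
    prior = BasePrior.from_genome(genome)
    bg = genome_kmer_fraction(genome, "C", 0)
    assert bg.pct_of_all_kmers == pytest.approx(100 * prior.p["C"])


def test_kmer_fraction_strand_symmetric():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    a = genome_kmer_fraction(Genome({"c": seq}), "TTCCT", 2)
    b = genome_kmer_fraction(Genome({"c": revcomp(seq)}), "TTCCT", 2)
    assert a.pct_of_all_kmers == pytest.approx(b.pct_of_all_kmers)


def test_kmer_fraction_skips_non_acgt_windows():
    bg = genome_kmer_fraction(Genome({"c": "CTNNCT"}), "CT", 0)
    assert bg.n_total == 4  # the NN-containing windows are dropped both strands


def test_kmer_fraction_rejects_oversized_motif():
    with pytest.raises(ValueError):
        genome_kmer_fraction(Genome({"c": "ACG"}), "ACGT", 0)


# ------------------------------------------------------------------ enrichment


def test_enrichment_identical_fractions_null():
    rng = np.random.default_rng(6)
    seqs = planted_contexts(rng, 200, "TTCTTT", 2, fraction=0.5)
    m = contexts_from(seqs)
    call = call_motif(relative_entropy(m, BasePrior.uniform()), m)
    res = motif_enrichment_test(m, m, call)
    assert res.chi2 == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_enrichment_planted_difference_detected():
    rng = np.random.default_rng(7)
    rec = contexts_from(planted_contexts(rng, 200, "TTCTTT", 2, fraction=0.8))
    non = contexts_from(planted_contexts(rng, 200, "TTCTTT", 2, fraction=0.5))
    call = call_motif(relative_entropy(rec, BasePrior.uniform()), rec)
    res = motif_enrichment_test(rec, non, call)
    assert res.pct_recurrent_with_motif > res.pct_nonrecurrent_with_motif
    assert res.p_value < 0.05


def test_sequence_has_motif_respects_iupac():
    rng = np.random.default_rng(8)
    m = contexts_from(planted_contexts(rng, 50, "TTCTTT", 2, fraction=1.0))
    call = call_motif(relative_entropy(m, BasePrior.uniform()), m)
    ctx = list("A" * 21)
    ctx[8:14] = "TTCTTT"
    assert sequence_has_motif("".join(ctx), 10, call)
    ctx[8] = "G"
    assert not sequence_has_motif("".join(ctx), 10, call)
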