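"""Synthetic reference genomes and mutation cohorts with known ground truth.

The generator emulates the statistical structure the recurrence analysis
assumes: samples are drawn from latent mutational-process archetypes that
differ in mutational load (log-normal, mirroring the orders-of-magnitude
spread of real cohorts), SSM subtype mix, sequence-context bias (a fraction
of one subtype's SSMs placed at planted motif occurrences), regional
concentration (a fraction placed on an archetype-wide hotspot list), and the
homopolymer-context profile of 1 bp indels.  Recurrence is never planted
directly: it emerges from placement concentration — shared motif sites,
shared hotspots, shared scarce homopolymer tracts — exactly the three causal
routes (load, sequence context, regional enrichment) the analysis is meant
to detect.

All randomness flows from a single seed through ``numpy`` SeedSequence
spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genome import Genome
from .io_context import (
    HOMOPOLYMER_CATEGORIES,
    MutationRecord,
    SIM_SUBTYPES,
    SSM_SUBTYPES,
    classify_homopolymer_run,
    normalize_mutations,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------- reference


@dataclass
class ReferenceSpec:
    """A synthetic reference: random base composition plus planted elements.

    ``homopolymer_tracts`` maps (base, length) to the number of tracts to
    plant (each flanked by guard bases of a different type so its class is
    exact); ``motif_occurrences`` maps a concrete ACGT motif string to its
    planted occurrence count.  Long homopolymers are scarce in random
    sequence, so planting them reproduces the scarcity structure that makes
    indel recurrence informative.
    """

    contig_length: int = 10_000_000
    n_contigs: int = 1
    gc_fraction: float = 0.40
    homopolymer_tracts: dict[tuple[str, int], int] = field(default_factory=dict)
    motif_occurrences: dict[str, int] = field(default_factory=dict)

    @classmethod
    def default(cls, contig_length: int = 10_000_000) -> "ReferenceSpec":
        tracts = {}
        for base in "ACGT":
            for length, count in ((8, 250), (9, 150), (10, 100)):
                tracts[(base, length)] = count
        return cls(
            contig_length=contig_length,
            homopolymer_tracts=tracts,
            motif_occurrences={"TTTCCT": 3000},
        )


def generate_reference(spec: ReferenceSpec, seed: int) -> tuple[Genome, pd.DataFrame]:
    """Generate the reference genome and its element map.

    Returns the genome and a BED-like table (chrom, start, end — 1-based
    inclusive — type, label, length) of planted homopolymer tracts and motif
    occurrences.  Deterministic under the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    contigs: dict[str, str] = {}
    elements = []
    for ci in range(spec.n_contigs):
        chrom = f"ctg{ci + 1}"
        arr = rng.choice(base_bytes, size=spec.contig_length, p=probs)
        occupied = np.zeros(spec.contig_length, dtype=bool)

        def _plant(payload: bytes, guard: bool, etype: str, label: str):
            width = len(payload) + (2 if guard else 0)
            if width > spec.contig_length:
                raise ValueError("planted element longer than contig")
            for _ in range(200):
                start0 = int(rng.integers(1, spec.contig_length - width - 1))
                if not occupied[start0 : start0 + width].any():
                    break
            else:
                raise ValueError("could not place planted element without overlap")
            occupied[start0 : start0 + width] = True
            content0 = start0 + (1 if guard else 0)
            if guard:
                tract_base = payload[:1]
                others = [b for b in b"ACGT" if bytes([b]) != tract_base]
                arr[start0] = rng.choice(others)
                arr[start0 + width - 1] = rng.choice(others)
            arr[content0 : content0 + len(payload)] = np.frombuffer(payload, dtype=np.uint8)
            elements.append(
                (chrom, content0 + 1, content0 + len(payload), etype, label, len(payload))
            )

        for (base, length), count in sorted(spec.homopolymer_tracts.items()):
            for _ in range(count):
                _plant((base * length).encode(), True, "homopolymer", base)
        for motif, count in sorted(spec.motif_occurrences.items()):
            if set(motif) - set("ACGT"):
                raise ValueError(f"planted motif must be concrete ACGT: {motif!r}")
            for _ in range(count):
                _plant(motif.encode(), False, "motif", motif)
        contigs[chrom] = arr.tobytes().decode("ascii")
    element_map = pd.DataFrame(
        elements, columns=["chrom", "start", "end", "type", "label", "length"]
    )
    return Genome(contigs), element_map


# ---------------------------------------------------------------- archetypes


@dataclass
class MotifBias:
    motif: str
    mutation_offset: int  # 0-based index of the mutated base within the motif
    subtype: str  # SSM subtype whose events are biased, e.g. "C>T"
    fraction: float  # share of that subtype's SSMs placed at motif occurrences


@dataclass
class HotspotBias:
    subtype: str
    fraction: float
    n_hotspots: int


_BACKGROUND_CONTEXT = {"none": 0.55, "short": 0.38, "midsize": 0.06, "long": 0.01}


@dataclass
class ProcessArchetype:
    """One latent mutational process: loads, mixes and placement biases.

    Loads are log-normal: ``count = round(median * exp(sigma * z))`` with
    standard-normal z.  ``sim_context_probs`` gives, per 1 bp SIM subtype,
    the distribution over homopolymer context classes the generator realizes
    by choosing runs of the matching class.
    """

    name: str
    ssm_load_median: float
    ssm_load_sigma: float
    sim_load_median: float
    sim_load_sigma: float
    ssm_subtype_probs: dict[str, float]
    sim_subtype_probs: dict[str, float] = field(
        default_factory=lambda: {s: 0.25 for s in SIM_SUBTYPES}
    )
    sim_context_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(_BACKGROUND_CONTEXT) for s in SIM_SUBTYPES}
    )
    motif_bias: Optional[MotifBias] = None
    hotspot_bias: Optional[HotspotBias] = None
    multi_bp_sim_fraction: float = 0.02

    def __post_init__(self):
        for probs in (self.ssm_subtype_probs, self.sim_subtype_probs,
                      *self.sim_context_probs.values()):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{self.name}: probabilities sum to {total}, not 1")


def uv_like() -> ProcessArchetype:
    """High load, C>T-dominant, strongly motif-biased (UV-light-like)."""
    return ProcessArchetype(
        name="uv-like",
        ssm_load_median=4000, ssm_load_sigma=0.3,
        sim_load_median=60, sim_load_sigma=0.4,
        ssm_subtype_probs={"C>A": 0.05, "C>G": 0.05, "C>T": 0.70,
                           "T>A": 0.05, "T>C": 0.10, "T>G": 0.05},
        motif_bias=MotifBias("TTTCCT", 4, "C>T", 0.35),
    )


def msi_like() -> ProcessArchetype:
    """Indel-heavy, midsize/long-homopolymer-biased (mismatch-repair-defective-like)."""
    ctx = {
        "C/G del": {"none": 0.05, "short": 0.10, "midsize": 0.73, "long": 0.12},
        "A/T del": {"none": 0.05, "short": 0.25, "midsize": 0.40, "long": 0.30},
        "A/T ins": {"none": 0.10, "short": 0.30, "midsize": 0.40, "long": 0.20},
        "C/G ins": {"none": 0.10, "short": 0.30, "midsize": 0.45, "long": 0.15},
    }
    return ProcessArchetype(
        name="msi-like",
        ssm_load_median=1200, ssm_load_sigma=0.3,
        sim_load_median=2500, sim_load_sigma=0.3,
        ssm_subtype_probs={"C>A": 0.10, "C>G": 0.05, "C>T": 0.40,
                           "T>A": 0.08, "T>C": 0.27, "T>G": 0.10},
        sim_subtype_probs={"A/T del": 0.35, "C/G del": 0.35,
                           "A/T ins": 0.20, "C/G ins": 0.10},
        sim_context_probs=ctx,
    )


def tobacco_like() -> ProcessArchetype:
    """High C>A load with no preferred sequence context (tobacco-smoke-like)."""
    return ProcessArchetype(
        name="tobacco-like",
        ssm_load_median=3500, ssm_load_sigma=0.3,
        sim_load_median=250, sim_load_sigma=0.4,
        ssm_subtype_probs={"C>A": 0.55, "C>G": 0.10, "C>T": 0.15,
                           "T>A": 0.08, "T>C": 0.08, "T>G": 0.04},
    )


def neutral() -> ProcessArchetype:
    """Low load, flat subtype mix, no placement bias."""
    return ProcessArchetype(
        name="neutral",
        ssm_load_median=600, ssm_load_sigma=0.3,
        sim_load_median=40, sim_load_sigma=0.4,
        ssm_subtype_probs={s: 1 / 6 for s in SSM_SUBTYPES},
    )


def default_archetypes() -> list[ProcessArchetype]:
    return [uv_like(), msi_like(), tobacco_like(), neutral()]


# ---------------------------------------------------------------- placement


class _PlacementIndex:
    """Per-genome lookup tables the generator draws placements from."""

    def __init__(self, genome: Genome, element_map: pd.DataFrame):
        self.genome = genome
        self.base_positions: dict[tuple[str, str], np.ndarray] = {}
        # (chrom, base, category) -> run starts (1-based, start >= 2 so an
        # anchor base exists and the run cannot extend 5')
        self.runs: dict[tuple[str, str, str], np.ndarray] = {}
        for chrom in genome.contigs:
            arr = np.frombuffer(genome.sequence(chrom).encode("ascii"), dtype=np.uint8)
            for base in "ACGT":
                self.base_positions[(chrom, base)] = np.flatnonzero(arr == ord(base)) + 1
            change = np.flatnonzero(arr[1:] != arr[:-1])
            starts = np.concatenate([[0], change + 1])
            lengths = np.diff(np.concatenate([starts, [len(arr)]]))
            run_bases = arr[starts]
            cats = np.select(
                [lengths <= 1, lengths <= 4, lengths <= 7],
                ["none", "short", "midsize"], default="long",
            )
            keep = starts >= 1
            for base in "ACGT":
                for cat in HOMOPOLYMER_CATEGORIES:
                    sel = keep & (run_bases == ord(base)) & (cats == cat)
                    self.runs[(chrom, base, cat)] = starts[sel] + 1
        motifs = element_map[element_map["type"] == "motif"]
        self.motif_sites: dict[str, pd.DataFrame] = {
            str(m): grp[["chrom", "start"]].reset_index(drop=True)
            for m, grp in motifs.groupby("label")
        }

    def ssm_positions(self, subtype: str) -> list[tuple[str, np.ndarray, str, str]]:
        """Per contig: positions compatible with a subtype on either strand."""
        pyr, alt = subtype[0], subtype[2]
        out = []
        for chrom in self.genome.contigs:
            out.append((chrom, self.base_positions[(chrom, pyr)], pyr, alt))
            out.append((chrom, self.base_positions[(chrom, _COMP[pyr])],
                        _COMP[pyr], _COMP[alt]))
        return out


# ---------------------------------------------------------------- cohort


@dataclass
class Cohort:
    """A generated cohort: raw calls, truth labels, and provenance."""

    calls: pd.DataFrame  # sample_id, chrom, pos, ref, alt
    truth: pd.DataFrame  # sample_id, archetype
    loads: pd.DataFrame  # sample_id, n_ssm_drawn, n_sim_drawn
    archetypes: list[ProcessArchetype]
    seed: int

    @property
    def truth_labels(self) -> pd.Series:
        return self.truth.set_index("sample_id")["archetype"]

    def to_records(self) -> list[MutationRecord]:
        rows = self.calls
        kinds = np.where(
            rows["ref"].str.len() == rows["alt"].str.len(), "SSM", "SIM"
        )
        return [
            MutationRecord(r.sample_id, r.chrom, int(r.pos), r.ref, r.alt, k)
            for r, k in zip(rows.itertuples(), kinds)
        ]

    def normalized(self, genome: Genome) -> pd.DataFrame:
        """The cohort as a normalized mutation table (left-aligned, classified)."""
        return normalize_mutations(self.to_records(), genome)

    def write_vcfs(self, outdir, genome: Genome) -> pd.DataFrame:
        """One plain-text VCF per sample plus a manifest TSV; returns the manifest."""
        import os

        os.makedirs(outdir, exist_ok=True)
        contig_lines = "".join(
            f"##contig=<ID={c},length={genome.length(c)}>\n" for c in genome.contigs
        )
        rows = []
        labels = self.truth_labels
        for sid, grp in self.calls.groupby("sample_id", sort=False):
            path = os.path.join(outdir, f"{sid}.vcf")
            grp = grp.sort_values(["chrom", "pos"])
            with open(path, "w") as fh:
                fh.write("##fileformat=VCFv4.2\n")
                fh.write(contig_lines)
                fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
                for r in grp.itertuples():
                    fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\n")
            rows.append((sid, path, labels[sid]))
        manifest = pd.DataFrame(rows, columns=["sample_id", "path", "tumour_type"])
        manifest.to_csv(os.path.join(outdir, "manifest.tsv"), sep="\t", index=False)
        return manifest


def _lognormal_count(rng, median: float, sigma: float) -> int:
    return max(0, int(round(median * np.exp(sigma * rng.standard_normal()))))


def _draw_hotspots(
    rng, placement: _PlacementIndex, bias: HotspotBias
) -> pd.DataFrame:
    frames = []
    for chrom, positions, ref, alt in placement.ssm_positions(bias.subtype):
        frames.append(pd.DataFrame({"chrom": chrom, "pos": positions,
                                    "ref": ref, "alt": alt}))
    pool = pd.concat(frames, ignore_index=True)
    take = rng.choice(len(pool), size=min(bias.n_hotspots, len(pool)), replace=False)
    return pool.iloc[np.sort(take)].reset_index(drop=True)


def generate_cohort(
    archetype_sizes: list[tuple[ProcessArchetype, int]],
    genome: Genome,
    element_map: pd.DataFrame,
    seed: int,
) -> Cohort:
    """Draw a cohort of samples from the given archetypes.

    For each sample: loads are drawn log-normally; motif-biased SSMs go to
    planted occurrences of the archetype's motif (the mutated offset carries
    the subtype's pyrimidine), hotspot-biased SSMs to the archetype's shared
    hotspot list, and the remainder uniformly over reference positions whose
    base is compatible with the subtype on either strand.  1 bp SIMs are
    realized by sampling mononucleotide runs of the demanded context class —
    emitted as left-aligned anchored VCF records — and a small fraction of
    SIMs is multi-bp.  Within a sample, duplicate mutation keys are dropped.
    """
    root = np.random.SeedSequence(seed)
    archetype_seeds = root.spawn(len(archetype_sizes))
    placement = _PlacementIndex(genome, element_map)
    all_rows: list[tuple] = []
    truth_rows = []
    load_rows = []
    for (arch, n_samples), arch_seed in zip(archetype_sizes, archetype_seeds):
        arch_rng = np.random.default_rng(arch_seed)
        hotspots = (
            _draw_hotspots(arch_rng, placement, arch.hotspot_bias)
            if arch.hotspot_bias else None
        )
        sample_seeds = arch_seed.spawn(n_samples)
        for si, s_seed in enumerate(sample_seeds):
            rng = np.random.default_rng(s_seed)
            sid = f"{arch.name}_{si:03d}"
            truth_rows.append((sid, arch.name))
            rows = _generate_sample(rng, sid, arch, placement, hotspots)
            load_rows.append((sid, sum(1 for r in rows if len(r[3]) == len(r[4])),
                              sum(1 for r in rows if len(r[3]) != len(r[4]))))
            all_rows.extend(rows)
    calls = pd.DataFrame(all_rows, columns=["sample_id", "chrom", "pos", "ref", "alt"])
    calls = calls.drop_duplicates(subset=["sample_id", "chrom", "pos", "ref", "alt"])
    return Cohort(
        calls=calls.reset_index(drop=True),
        truth=pd.DataFrame(truth_rows, columns=["sample_id", "archetype"]),
        loads=pd.DataFrame(load_rows, columns=["sample_id", "n_ssm_drawn", "n_sim_drawn"]),
        archetypes=[a for a, _ in archetype_sizes],
        seed=seed,
    )


def _generate_sample(rng, sid, arch, placement, hotspots) -> list[tuple]:
    genome = placement.genome
    rows: list[tuple] = []
    # --- SSMs
    n_ssm = _lognormal_count(rng, arch.ssm_load_median, arch.ssm_load_sigma)
    probs = [arch.ssm_subtype_probs.get(s, 0.0) for s in SSM_SUBTYPES]
    subtype_counts = rng.multinomial(n_ssm, probs)
    for subtype, count in zip(SSM_SUBTYPES, subtype_counts):
        if count == 0:
            continue
        remaining = count
        mb = arch.motif_bias
        if mb and mb.subtype == subtype:
            n_motif = rng.binomial(count, mb.fraction)
            sites = placement.motif_sites.get(mb.motif)
            if sites is None or sites.empty:
                raise ValueError(f"motif {mb.motif} absent from the reference")
            picks = rng.integers(0, len(sites), size=n_motif)
            pyr, alt = subtype[0], subtype[2]
            for i in picks:
                site = sites.iloc[int(i)]
                pos = int(site["start"]) + mb.mutation_offset
                ref = genome.base(site["chrom"], pos)
                if ref == pyr:
                    rows.append((sid, site["chrom"], pos, ref, alt))
                else:  # motif planted with the purine partner at the offset
                    rows.append((sid, site["chrom"], pos, ref, _COMP[alt]))
            remaining -= n_motif
        hb = arch.hotspot_bias
        if hb and hb.subtype == subtype and hotspots is not None:
            n_hot = rng.binomial(remaining, min(1.0, hb.fraction))
            picks = rng.integers(0, len(hotspots), size=n_hot)
            for i in picks:
                h = hotspots.iloc[int(i)]
                rows.append((sid, h["chrom"], int(h["pos"]), h["ref"], h["alt"]))
            remaining -= n_hot
        pools = placement.ssm_positions(subtype)
        sizes = np.array([len(p[1]) for p in pools], dtype=float)
        weights = sizes / sizes.sum()
        counts = rng.multinomial(remaining, weights)
        for (chrom, positions, ref, alt), m in zip(pools, counts):
            if m == 0:
                continue
            for pos in positions[rng.integers(0, len(positions), size=m)]:
                rows.append((sid, chrom, int(pos), ref, alt))
    # --- SIMs
    n_sim = _lognormal_count(rng, arch.sim_load_median, arch.sim_load_sigma)
    n_multi = rng.binomial(n_sim, arch.multi_bp_sim_fraction)
    n_1bp = n_sim - n_multi
    sub_probs = [arch.sim_subtype_probs.get(s, 0.0) for s in SIM_SUBTYPES]
    for subtype, count in zip(SIM_SUBTYPES, rng.multinomial(n_1bp, sub_probs)):
        if count == 0:
            continue
        ctx_probs = arch.sim_context_probs[subtype]
        cat_counts = rng.multinomial(
            count, [ctx_probs.get(c, 0.0) for c in HOMOPOLYMER_CATEGORIES]
        )
        pair = ("A", "T") if subtype.startswith("A/T") else ("C", "G")
        is_del = subtype.endswith("del")
        for cat, m in zip(HOMOPOLYMER_CATEGORIES, cat_counts):
            for _ in range(int(m)):
                base = pair[rng.integers(0, 2)]
                rows.append(_place_sim(rng, sid, placement, base, cat, is_del))
    for _ in range(n_multi):
        k = int(rng.integers(2, 4))
        chrom = genome.contigs[int(rng.integers(0, len(genome.contigs)))]
        pos = int(rng.integers(1, genome.length(chrom) - k))
        ref = genome.fetch(chrom, pos, pos + k)
        rows.append((sid, chrom, pos, ref, ref[0]))
    return rows


def _place_sim(rng, sid, placement, base, category, is_del) -> tuple:
    genome = placement.genome
    for chrom_try in rng.permutation(genome.contigs):
        runs = placement.runs.get((chrom_try, base, category))
        if runs is not None and len(runs):
            start = int(runs[rng.integers(0, len(runs))])
            anchor = start - 1
            anchor_base = genome.base(chrom_try, anchor)
            if is_del:
                return (sid, chrom_try, anchor, anchor_base + base, anchor_base)
            if category == "none":
                # An insertion's run counts only 3' reference bases, so a
                # "none" context also allows inserting before a non-matching
                # base; inserting before a length-1 run realizes run_length 1.
                pass
            return (sid, chrom_try, anchor, anchor_base, anchor_base + base)
    raise ValueError(f"no run of {base!r} with context {category!r} in the reference")


@dataclass
class TruthReport:
    ari: float
    confusion: pd.DataFrame  # archetype x cluster counts


def truth_report(truth_labels: pd.Series, assignments: pd.Series) -> TruthReport:
    """Adjusted Rand index and confusion table of assignments against truth."""
    from sklearn.metrics import adjusted_rand_score

    if set(truth_labels.index) != set(assignments.index):
        raise ValueError("truth and assignments cover different sample sets")
    truth = truth_labels.loc[assignments.index]
    ari = float(adjusted_rand_score(truth.to_numpy(), assignments.to_numpy()))
    confusion = pd.crosstab(truth, assignments)
    return TruthReport(ari=ari, confusion=confusion)
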