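"""Reference-sequence access.

All public coordinates in this package are 1-based and inclusive, following
VCF convention; the conversion to Python's 0-based slices happens only here.
Chromosome names are matched after stripping any leading ``chr`` prefix, and
soft-masked (lowercase) bases are uppercased on load, so masking is ignored.
"""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters beyond ACGTN not supported)."""
    return seq.translate(COMPLEMENT)[::-1]


def _norm_chrom(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


class Genome:
    """In-memory reference genome with 1-based inclusive coordinate access.

    Sequences are held as plain uppercase strings; for the genome sizes this
    package targets (toy/synthetic references up to tens of Mb) this is both
    simplest and fastest.  Use :meth:`from_fasta` for on-disk references.
    """

    def __init__(self, contigs: dict[str, str]):
        self._seqs = {_norm_chrom(name): seq.upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return _norm_chrom(chrom) in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[_norm_chrom(chrom)])

    def sequence(self, chrom: str) -> str:
        """The full contig sequence."""
        return self._seqs[_norm_chrom(chrom)]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases ``start..end`` (1-based, inclusive).  Out-of-range raises."""
        seq = self._seqs[_norm_chrom(chrom)]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(
                f"coordinates {chrom}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)
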