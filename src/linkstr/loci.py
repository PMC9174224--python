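"""Target STR loci: the repeat regions to be genotyped.

A locus is a reference interval plus its repeat motif.  All coordinates in
this package are 0-based half-open (BED convention); human-readable region
strings are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class StrLocus:
    """A short-tandem-repeat locus on the reference genome.

    Parameters
    ----------
    chrom : str
        Reference sequence name.
    start, end : int
        0-based half-open interval of the repeat tract in the reference.
    motif : str
        Repeat unit, uppercase ACGT (e.g. ``"ATTCT"`` for ATXN10-type loci).
    name : str
        Optional label carried through reports.
    """

    chrom: str
    start: int
    end: int
    motif: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid locus interval {self.chrom}:{self.start}-{self.end}"
            )
        motif = self.motif.upper()
        if not motif or not set(motif) <= _VALID_BASES:
            raise ValueError(f"invalid repeat motif {self.motif!r}: must be non-empty ACGT")
        object.__setattr__(self, "motif", motif)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def region(self) -> str:
        """1-based inclusive region string (samtools style)."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def read_loci_bed(path: str) -> list[StrLocus]:
    """Read target loci from a BED4+ file (column 4 = repeat motif).

    Blank lines and ``#``/``track``/``browser`` lines are skipped.  Malformed
    lines raise :class:`ValueError` naming the offending line number.
    """
    loci: list[StrLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns "
                    f"(chrom, start, end, motif), got {len(fields)}"
                )
            chrom, start_s, end_s, motif = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[4] if len(fields) > 4 else ""
            try:
                loci.append(StrLocus(chrom, start, end, motif, name=name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return loci


def write_loci_bed(loci: list[StrLocus], path: str) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fields = [loc.chrom, str(loc.start), str(loc.end), loc.motif]
            if loc.name:
                fields.append(loc.name)
            fh.write("\t".join(fields) + "\n")
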