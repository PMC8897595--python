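"""miRNA seed-site motif derivation and satellite-region scanning.

A miRNA's *seed* is nucleotides 2-8 of its mature sequence.  The canonical
target-site taxonomy defines, on the target DNA read 5'->3':

- **8mer**: perfect Watson-Crick match to miRNA positions 2-8, followed by an
  adenine opposite miRNA position 1 — i.e. reverse complement (in DNA) of
  positions 2-8, then ``A``.
- **7mer-m8**: the same without the trailing ``A``.
- **7mer-A1**: reverse complement of positions 2-7, then ``A``.

Sites are counted by an overlapping sliding window; ``N`` bases never match.
miRNAs with identical mature seeds (e.g. miR-30a/d/e-3p) produce identical
motifs and therefore identical counts — a property the tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MiRnaRecord",
    "SeedMotif",
    "SITE_TYPES",
    "read_mirnas",
    "seed_motif",
    "count_sites",
    "scan_regions",
    "rank_mirnas",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_RNA_ALPHABET = set("ACGU")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(dna: str) -> str:
    """Reverse complement of an ACGT(N) string (N maps to N)."""
    return dna.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class MiRnaRecord:
    """A mature miRNA: id plus 5'->3' RNA sequence (A/C/G/U, length >= 8)."""

    id: str
    mature_sequence: str

    def __post_init__(self) -> None:
        seq = self.mature_sequence.upper()
        object.__setattr__(self, "mature_sequence", seq)
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ValueError(
                f"miRNA {self.id}: invalid RNA characters {sorted(bad)}"
            )
        if len(seq) < 8:
            raise ValueError(
                f"miRNA {self.id}: mature sequence must be >= 8 nt for seed "
                f"derivation, got {len(seq)}"
            )


@dataclass(frozen=True)
class SeedMotif:
    """A target-site DNA motif (read 5'->3' on the target strand)."""

    mirna_id: str
    site_type: str
    motif: str


def read_mirnas(path: str | Path) -> list[MiRnaRecord]:
    """Read mature miRNAs from FASTA or a two-column (id, sequence) TSV.

    The format is sniffed from the first non-blank character (``>`` = FASTA).
    ``T`` in input sequences is accepted and converted to ``U``.
    """
    path = Path(path)
    text = path.read_text()
    first = next((c for c in text if not c.isspace()), "")
    records: list[MiRnaRecord] = []
    if first == ">":
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(
                MiRnaRecord(rec.id, str(rec.seq).upper().replace("T", "U"))
            )
    else:
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"expected two tab-separated columns: {line!r}")
            records.append(
                MiRnaRecord(fields[0].strip(), fields[1].strip().upper().replace("T", "U"))
            )
    return records


def seed_motif(mirna: MiRnaRecord, site_type: str = "8mer") -> SeedMotif:
    """Derive the target-site motif for one miRNA.

    The seed region (miRNA positions 2-8, 1-based) is converted to DNA and
    reverse-complemented; 8mer and 7mer-A1 motifs append the adenine found
    opposite miRNA position 1 in canonical sites.
    """
    if site_type not in SITE_TYPES:
        raise ValueError(f"site_type must be one of {SITE_TYPES}, got {site_type!r}")
    seed_dna = mirna.mature_sequence.replace("U", "T")
    if site_type == "8mer":
        motif = reverse_complement(seed_dna[1:8]) + "A"
    elif site_type == "7mer-m8":
        motif = reverse_complement(seed_dna[1:8])
    else:  # 7mer-A1
        motif = reverse_complement(seed_dna[1:7]) + "A"
    return SeedMotif(mirna_id=mirna.id, site_type=site_type, motif=motif)


def count_sites(
    sequence: str, motif: SeedMotif | str, strand_mode: str = "annotated"
) -> dict[str, int]:
    """Count overlapping motif occurrences in a DNA sequence.

    Parameters
    ----------
    sequence:
        Target DNA (A/C/G/T/N; ``N`` never matches).
    motif:
        A :class:`SeedMotif` or a plain DNA string.
    strand_mode:
        ``"annotated"`` scans the given strand only and returns ``{"+": n}``;
        ``"both"`` additionally scans the reverse complement and returns
        per-strand counts ``{"+": n, "-": m}``.

    Occurrences are counted with a fully overlapping sliding window: in
    ``"AAAAAAAAAA"`` the motif ``"AAAAAAAA"`` occurs 3 times.
    """
    pattern = motif.motif if isinstance(motif, SeedMotif) else motif
    if not pattern:
        raise ValueError("empty motif")
    seq = sequence.upper()
    counts = {"+": _count_overlapping(seq, pattern)}
    if strand_mode == "both":
        # a minus-strand site is an occurrence of the motif's reverse
        # complement on the given (plus) strand
        counts["-"] = _count_overlapping(seq, reverse_complement(pattern))
    elif strand_mode != "annotated":
        raise ValueError(f"strand_mode must be 'annotated' or 'both', got {strand_mode!r}")
    return counts


def _count_overlapping(sequence: str, pattern: str) -> int:
    count = 0
    start = sequence.find(pattern)
    while start != -1:
        count += 1
        start = sequence.find(pattern, start + 1)
    return count


def scan_regions(
    mirnas: Iterable[MiRnaRecord],
    regions: Sequence,
    site_type: str = "8mer",
    strand_mode: str = "both",
) -> pd.DataFrame:
    """Count seed sites for each miRNA in each satellite region.

    ``regions`` are :class:`majorsat.repeats.SatelliteRegion` objects with
    attached sequences (a region without sequence raises ``ValueError``).
    Returns a tidy table with one row per miRNA x region (x strand):
    columns ``mirna_id, site_type, motif, region_id, strand, count``.
    """
    for r in regions:
        if r.sequence is None:
            raise ValueError(f"region {r.region_id} has no attached sequence")
    rows = []
    for mirna in mirnas:
        m = seed_motif(mirna, site_type)
        for r in regions:
            counts = count_sites(r.sequence, m, strand_mode=strand_mode)
            for strand, n in counts.items():
                rows.append(
                    {
                        "mirna_id": m.mirna_id,
                        "site_type": site_type,
                        "motif": m.motif,
                        "region_id": r.region_id,
                        "strand": strand,
                        "count": n,
                    }
                )
    return pd.DataFrame(
        rows, columns=["mirna_id", "site_type", "motif", "region_id", "strand", "count"]
    )


def rank_mirnas(table: pd.DataFrame, top_n: int = 5) -> pd.DataFrame:
    """Rank miRNAs by total site count (descending), ties broken by id.

    ``table`` is the output of :func:`scan_regions`.  Returns the top ``top_n``
    miRNAs (all of them if ``top_n`` exceeds the table) with columns
    ``mirna_id, total, rank`` plus a per-region breakdown in wide columns.
    """
    if table.empty:
        return pd.DataFrame(columns=["mirna_id", "total", "rank"])
    totals = (
        table.groupby("mirna_id")["count"]
        .sum()
        .reset_index()
        .rename(columns={"count": "total"})
        .sort_values(["total", "mirna_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    totals["rank"] = range(1, len(totals) + 1)
    per_region = (
        table.groupby(["mirna_id", "region_id"])["count"].sum().unstack(fill_value=0)
    )
    ranked = totals.head(top_n).merge(per_region, on="mirna_id", how="left")
    return ranked
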