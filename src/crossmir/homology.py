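"""Cross-species mature miRNA homology by exact sequence identity.

Mature miRNAs (~22 nt) are short enough that orthology between mouse and
human can be called by requiring *perfect* identity of the mature sequence —
same length, same nucleotides.  This module parses miRBase-style mature
FASTA (header ``name accession description``, e.g. ``>mmu-miR-17
MIMAT0000649 Mus musculus miR-17``), normalizes sequences to the uppercase
RNA alphabet, and pairs records across species whose normalized sequences
are identical strings.

A sequence shared by several mature names produces several pairs
(multi-mapping); :func:`count_conserved` exposes both the per-name and
per-sequence counting conventions.  Matching by *name* instead of sequence
is available as an explicitly labelled fallback for platforms that ship no
sequences; it is never used by default.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

__all__ = [
    "MatureMiRNA",
    "HomologyMap",
    "FastaParseError",
    "normalize_sequence",
    "parse_mature_fasta",
    "read_mature_fasta",
    "find_homologs",
    "find_homologs_by_name",
    "seed_region",
    "count_conserved",
    "write_homology_tsv",
]

_RNA_ALPHABET = frozenset("ACGU")


class FastaParseError(ValueError):
    """Raised for malformed mature-FASTA input (e.g. a header with no name)."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map DNA thymine to RNA uracil.

    miRBase mature files are RNA-alphabet but user-supplied fixtures are
    often DNA-alphabet; matching is always performed on the normalized form.

    Raises
    ------
    ValueError
        If the normalized sequence is empty or contains characters outside
        ``{A, C, G, U}``.
    """
    norm = seq.strip().upper().replace("T", "U")
    if not norm:
        raise ValueError("empty sequence")
    bad = set(norm) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    return norm


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA record: miRBase name, accession, normalized sequence.

    ``species_prefix`` is the token before the first hyphen of the name
    (``"mmu"`` for mouse, ``"hsa"`` for human).
    """

    name: str
    sequence: str
    accession: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if not self.name:
            raise ValueError("mature miRNA name must be non-empty")

    @property
    def species_prefix(self) -> str:
        return self.name.split("-", 1)[0]


@dataclass
class HomologyMap:
    """Exact-identity cross-species pairing of mature miRNAs.

    ``pairs`` holds ``(mouse_name, human_name)`` tuples whose mature
    sequences are identical strings; ``unmatched_mouse``/``unmatched_human``
    partition the remaining names.  ``sequences`` maps every input name to
    its normalized sequence (used when serializing the map).
    """

    pairs: set[tuple[str, str]]
    unmatched_mouse: set[str]
    unmatched_human: set[str]
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def matched_mouse(self) -> set[str]:
        return {m for m, _ in self.pairs}

    @property
    def matched_human(self) -> set[str]:
        return {h for _, h in self.pairs}


def parse_mature_fasta(text: str) -> list[MatureMiRNA]:
    """Parse miRBase mature-FASTA text into :class:`MatureMiRNA` records.

    The header's first whitespace-delimited token is the mature name; the
    optional second token is taken as the MIMAT accession.  Sequences are
    normalized (uppercase, T→U); input order is preserved.  Duplicate
    identical headers trigger a warning but both records are kept.

    Raises
    ------
    FastaParseError
        For a header line carrying no name token, naming the line number.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">") and not line[1:].strip():
            raise FastaParseError(f"FASTA header with no name token at line {lineno}")

    records: list[MatureMiRNA] = []
    seen_headers: set[str] = set()
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        header = rec.description
        if header in seen_headers:
            warnings.warn(f"duplicate FASTA header kept: {header!r}", stacklevel=2)
        seen_headers.add(header)
        tokens = header.split()
        accession = tokens[1] if len(tokens) > 1 else ""
        try:
            records.append(MatureMiRNA(name=rec.id, sequence=str(rec.seq), accession=accession))
        except ValueError as exc:
            raise FastaParseError(f"record {rec.id!r}: {exc}") from exc
    return records


def read_mature_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Read a mature FASTA file from disk (see :func:`parse_mature_fasta`)."""
    return parse_mature_fasta(Path(path).read_text())


def _validate_species(records: Iterable[MatureMiRNA], prefix: str, role: str) -> None:
    for rec in records:
        if rec.species_prefix != prefix:
            raise ValueError(
                f"{role} list contains record {rec.name!r} with species prefix "
                f"{rec.species_prefix!r}, expected {prefix!r}"
            )


def find_homologs(
    mouse: list[MatureMiRNA],
    human: list[MatureMiRNA],
    *,
    mouse_prefix: str = "mmu",
    human_prefix: str = "hsa",
) -> HomologyMap:
    """Pair mouse and human mature miRNAs with identical sequences.

    Homology is called only on perfect identity in both length and
    nucleotide sequence.  Species prefixes are validated, not assumed.
    A sequence shared by several mature names in either species yields one
    pair per cross-species name combination.

    Raises
    ------
    ValueError
        If a record carries the wrong species prefix for its list.
    """
    _validate_species(mouse, mouse_prefix, "mouse")
    _validate_species(human, human_prefix, "human")

    by_seq_human: dict[str, list[str]] = {}
    for rec in human:
        by_seq_human.setdefault(rec.sequence, []).append(rec.name)

    pairs: set[tuple[str, str]] = set()
    for rec in mouse:
        for hname in by_seq_human.get(rec.sequence, ()):
            pairs.add((rec.name, hname))

    matched_m = {m for m, _ in pairs}
    matched_h = {h for _, h in pairs}
    sequences = {rec.name: rec.sequence for rec in [*mouse, *human]}
    return HomologyMap(
        pairs=pairs,
        unmatched_mouse={r.name for r in mouse} - matched_m,
        unmatched_human={r.name for r in human} - matched_h,
        sequences=sequences,
    )


def find_homologs_by_name(
    mouse: list[MatureMiRNA],
    human: list[MatureMiRNA],
) -> HomologyMap:
    """FALLBACK: pair records whose names match after stripping the species prefix.

    This ignores sequences entirely and exists only for platforms that ship
    no mature sequences.  It is *not* sequence homology and is never used by
    the default analysis path; prefer :func:`find_homologs`.
    """
    def stem(name: str) -> str:
        return name.split("-", 1)[1] if "-" in name else name

    by_stem_human: dict[str, list[str]] = {}
    for rec in human:
        by_stem_human.setdefault(stem(rec.name), []).append(rec.name)

    pairs = {
        (m.name, h)
        for m in mouse
        for h in by_stem_human.get(stem(m.name), ())
    }
    matched_m = {m for m, _ in pairs}
    matched_h = {h for _, h in pairs}
    return HomologyMap(
        pairs=pairs,
        unmatched_mouse={r.name for r in mouse} - matched_m,
        unmatched_human={r.name for r in human} - matched_h,
        sequences={rec.name: rec.sequence for rec in [*mouse, *human]},
    )


def seed_region(m: MatureMiRNA) -> str:
    """Return the seed region: nucleotides 2-8 (1-based, inclusive), a 7-mer.

    The seed is the principal target-recognition element of a mature miRNA.

    Raises
    ------
    ValueError
        If the mature sequence is shorter than 8 nt.
    """
    if len(m.sequence) < 8:
        raise ValueError(
            f"{m.name}: sequence length {len(m.sequence)} < 8, seed undefined"
        )
    return m.sequence[1:8]


def count_conserved(
    hmap: HomologyMap,
    *,
    species: Literal["mouse", "human"] = "mouse",
    convention: Literal["per_name", "per_sequence"] = "per_name",
) -> int:
    """Count conserved mature miRNAs under an explicit counting convention.

    ``per_name`` counts matched mature names in the chosen species (a
    sequence shared by several names counts each name); ``per_sequence``
    counts distinct conserved sequences once.
    """
    if convention == "per_sequence":
        return len({hmap.sequences[m] for m, _ in hmap.pairs})
    matched = hmap.matched_mouse if species == "mouse" else hmap.matched_human
    return len(matched)


def write_homology_tsv(hmap: HomologyMap, path: str | Path) -> None:
    """Write the homology map as TSV: mouse_name, human_name, sequence, length."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["mouse_name", "human_name", "sequence", "length"])
        for mouse_name, human_name in sorted(hmap.pairs):
            seq = hmap.sequences.get(mouse_name, "")
            writer.writerow([mouse_name, human_name, seq, len(seq)])
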