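"""Mouse-human concordance of differential-expression calls and overlap testing.

Given per-study direction calls (Up/Down, with Absent meaning the study did
not report the miRNA as differentially expressed), this module restricts
calls to conserved miRNAs, builds the mouse-vs-human concordance table, and
tests DE-list overlap with the upper-tail hypergeometric distribution.

A miRNA is Concordant when its mouse direction agrees with *every* human
study that reports it; a single opposite human call makes it Discordant.
When the human studies disagree with each other the row is flagged
(``conflict_within_human``) and counted Discordant regardless of the mouse
direction.  The hypergeometric universe (how many conserved miRNAs could in
principle appear in both lists) is a required explicit argument: it changes
the p-value and is never defaulted silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .homology import HomologyMap

__all__ = [
    "DirectionCall",
    "ConcordanceRow",
    "OverlapTest",
    "strip_species_prefix",
    "restrict_to_conserved",
    "build_concordance_table",
    "concordance_summary",
    "concordance_frame",
    "hypergeometric_overlap",
    "compare_de_lists",
    "read_direction_calls",
    "load_table1",
]

Direction = Literal["Up", "Down", "Absent"]

_SPECIES_PREFIXES = {"mmu", "hsa", "rno", "mml", "ptr"}


@dataclass(frozen=True)
class DirectionCall:
    """One study's differential-expression direction for one miRNA."""

    mirna: str
    study: str
    direction: Direction

    def __post_init__(self) -> None:
        if self.direction not in ("Up", "Down", "Absent"):
            raise ValueError(f"invalid direction {self.direction!r}")


@dataclass(frozen=True)
class ConcordanceRow:
    """Mouse-vs-human agreement for one conserved miRNA.

    ``label`` is Concordant iff every non-Absent human direction equals the
    mouse direction and the human studies do not conflict among themselves.
    """

    mirna: str
    mouse_dir: Direction
    human_dirs: Mapping[str, Direction]
    label: Literal["Concordant", "Discordant"]
    conflict_within_human: bool = False


@dataclass(frozen=True)
class OverlapTest:
    """Upper-tail hypergeometric overlap between two lists in a finite universe."""

    universe_n: int
    list_a_k: int
    list_b_n: int
    overlap_k: int
    p_value: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def strip_species_prefix(name: str) -> str:
    """Harmonize a mature name to a species-neutral key ('mmu-miR-17' -> 'miR-17')."""
    head, _, tail = name.partition("-")
    if tail and head.lower() in _SPECIES_PREFIXES:
        return tail
    return name


def restrict_to_conserved(
    calls: Sequence[DirectionCall],
    hmap: HomologyMap,
) -> tuple[list[DirectionCall], list[DirectionCall]]:
    """Keep calls whose miRNA participates in >= 1 homology pair.

    Identifiers are harmonized to a species-neutral key (species prefix
    stripped).  Returns ``(kept, rejects)``; non-conserved or unresolvable
    calls go to the rejects report rather than raising.
    """
    conserved_keys = {strip_species_prefix(m) for m, _ in hmap.pairs}
    conserved_keys |= {strip_species_prefix(h) for _, h in hmap.pairs}
    kept: list[DirectionCall] = []
    rejects: list[DirectionCall] = []
    for call in calls:
        key = strip_species_prefix(call.mirna)
        if key in conserved_keys:
            kept.append(DirectionCall(key, call.study, call.direction))
        else:
            rejects.append(call)
    return kept, rejects


def _collapse(calls: Iterable[DirectionCall], study: str) -> dict[str, Direction]:
    out: dict[str, Direction] = {}
    for call in calls:
        if call.direction == "Absent":
            continue
        prev = out.get(call.mirna)
        if prev is not None and prev != call.direction:
            raise ValueError(
                f"conflicting duplicate calls for {call.mirna!r} in study {study!r}: "
                f"{prev} vs {call.direction}"
            )
        out[call.mirna] = call.direction
    return out


def build_concordance_table(
    mouse: Sequence[DirectionCall],
    human_by_study: Mapping[str, Sequence[DirectionCall]],
) -> list[ConcordanceRow]:
    """Classify each mouse-DE miRNA against the human studies that report it.

    One row per miRNA present in the mouse list AND reported (non-Absent)
    by at least one human study.  Rows are ordered mouse-Up first, then
    mouse-Down, keeping input order within each block.

    Raises
    ------
    ValueError
        On conflicting duplicate calls within a single study.
    """
    mouse_dir = _collapse(mouse, "mouse")
    human_dirs = {study: _collapse(calls, study) for study, calls in human_by_study.items()}

    rows: list[ConcordanceRow] = []
    for mirna, mdir in mouse_dir.items():
        dirs: dict[str, Direction] = {
            study: human_dirs[study].get(mirna, "Absent") for study in human_by_study
        }
        reported = {d for d in dirs.values() if d != "Absent"}
        if not reported:
            continue
        conflict = len(reported) > 1
        label = "Concordant" if (not conflict and reported == {mdir}) else "Discordant"
        rows.append(ConcordanceRow(mirna, mdir, dirs, label, conflict))

    rows.sort(key=lambda r: 0 if r.mouse_dir == "Up" else 1)  # stable: input order kept
    return rows


def concordance_summary(rows: Sequence[ConcordanceRow]) -> tuple[int, int]:
    """Return (n_concordant, n_discordant)."""
    n_con = sum(r.label == "Concordant" for r in rows)
    return n_con, len(rows) - n_con


def concordance_frame(rows: Sequence[ConcordanceRow]) -> pd.DataFrame:
    """Tabulate concordance rows (one column per human study) for export."""
    studies = sorted({s for r in rows for s in r.human_dirs})
    records = []
    for r in rows:
        rec = {"mirna": r.mirna, "mouse_dir": r.mouse_dir}
        for s in studies:
            d = r.human_dirs.get(s, "Absent")
            rec[s] = "" if d == "Absent" else d
        rec["label"] = r.label
        rec["conflict_within_human"] = r.conflict_within_human
        records.append(rec)
    return pd.DataFrame(records).set_index("mirna")


def hypergeometric_overlap(
    universe_n: int,
    list_a_k: int,
    list_b_n: int,
    overlap_k: int,
) -> OverlapTest:
    """Upper-tail hypergeometric probability P(X >= k) of the observed overlap.

    With a universe of N items, K in list A and n drawn for list B, the
    tail sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n) is evaluated in
    log space (gammaln + logsumexp) for numerical stability at large N.
    """
    N, K, n, k = universe_n, list_a_k, list_b_n, overlap_k
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"list sizes K={K}, n={n} must lie in [0, N={N}]")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return OverlapTest(N, K, n, k, 1.0)

    def log_comb(a: int, b: int) -> float:
        return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))

    i = np.arange(k, min(K, n) + 1)
    log_terms = [log_comb(K, j) + log_comb(N - K, n - j) - log_comb(N, n)
                 for j in i if n - j <= N - K]
    p = float(np.exp(logsumexp(log_terms))) if log_terms else 0.0
    return OverlapTest(N, K, n, k, min(1.0, p))


def compare_de_lists(
    mouse_de: Sequence[str],
    human_de: Sequence[str],
    universe: Sequence[str],
) -> tuple[OverlapTest, pd.DataFrame]:
    """Set-intersect two DE lists within an explicit universe and test overlap.

    Returns the hypergeometric test plus a per-miRNA membership table
    (in_mouse / in_human / in_overlap).  Every list element must be in the
    universe; the offender is named otherwise.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    for label, lst in (("mouse", mouse_de), ("human", human_de)):
        for m in lst:
            if m not in uni_set:
                raise ValueError(f"{label} DE list element {m!r} not in universe")
    mouse_set, human_set = set(mouse_de), set(human_de)
    overlap = mouse_set & human_set
    test = hypergeometric_overlap(len(uni), len(mouse_set), len(human_set), len(overlap))
    membership = pd.DataFrame(
        {
            "in_mouse": [m in mouse_set for m in uni],
            "in_human": [m in human_set for m in uni],
            "in_overlap": [m in overlap for m in uni],
        },
        index=pd.Index(uni, name="mirna"),
    )
    return test, membership


def read_direction_calls(path: str | Path) -> tuple[list[DirectionCall], dict[str, list[DirectionCall]]]:
    """Read a direction-call TSV: mirna, mouse_dir, then one column per human study.

    Empty cells encode Absent.  Returns (mouse calls, human calls keyed by
    study column name).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "mirna" or df.columns[1] != "mouse_dir":
        raise ValueError("expected columns: mirna, mouse_dir, <study>...")
    studies = list(df.columns[2:])
    mouse: list[DirectionCall] = []
    human: dict[str, list[DirectionCall]] = {s: [] for s in studies}
    for _, row in df.iterrows():
        if row["mouse_dir"]:
            mouse.append(DirectionCall(row["mirna"], "mouse", row["mouse_dir"]))
        for s in studies:
            if row[s]:
                human[s].append(DirectionCall(row["mirna"], s, row[s]))
    return mouse, human


def load_table1() -> tuple[list[DirectionCall], dict[str, list[DirectionCall]]]:
    """Load the packaged mouse/human direction-call comparison table (29 miRNAs).

    The fixture encodes, for each conserved miRNA differentially expressed
    in mouse tumors, its mouse direction and the directions reported by the
    two published human MNA-vs-non-MNA profiling studies (Bray, Mestdagh);
    an empty cell means that study did not report the miRNA.
    """
    path = resources.files("crossmir.data").joinpath("table1_mouse_human.tsv")
    with resources.as_file(path) as p:
        return read_direction_calls(p)
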