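"""Synthetic qPCR-array Ct data with known ground truth.

No public accession exists for raw Ct data of this study design, so the
generator emulates its statistical structure directly: per-miRNA baseline
Cts drawn uniformly from 20-34 cycles, per-sample global Ct shifts
(Normal, SD 1 cycle — the loading/efficiency artifact that global-mean
centering exists to remove), planted two-group effects expressed in cycles
(1 cycle = 2-fold, so a planted log2 fold change of 2 is a 2-cycle Ct
shift, *downward* for over-expressed miRNAs), Gaussian Ct noise, and
right-censoring: any Ct above the detection limit (35) is reported as
Undetermined.

Defaults mirror the profiled design: 591 miRNAs, 22 tumors vs 12 adrenal
controls, 81 over- and 78 under-expressed miRNAs planted at |log2FC| = 2
with sigma_Ct = 0.5.  Two-species mode adds a human cohort (36 MNA vs 110
non-MNA), synthetic mature sequences that are identical for conserved
pairs and unique otherwise, and a planted concordant/discordant split
(29 conserved DE, 7 of them direction-flipped in human — the shape of the
published mouse/human comparison).

All randomness flows through one numpy Generator seeded from
``SyntheticSpec.seed``; the same spec always yields identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexp import DEResult
from .preprocess import CtMatrix

__all__ = [
    "SyntheticSpec",
    "TruthTable",
    "simulate_ct_matrix",
    "simulate_two_species",
    "evaluate_against_truth",
]

_RNA = np.array(list("ACGU"))


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic Ct-array study.

    Units: Ct values, baselines, effects, shifts and noise are all in qPCR
    cycles; ``effect_log2fc`` is the planted log2 fold change (equal in
    magnitude to the Ct displacement since one cycle is two-fold).
    """

    n_mirnas: int = 591
    group_sizes: tuple[int, int] = (22, 12)  # tumors, adrenal controls
    n_de_up: int = 81
    n_de_down: int = 78
    effect_log2fc: float = 2.0
    sigma_ct: float = 0.5
    sample_shift_sd: float = 1.0
    baseline_range: tuple[float, float] = (20.0, 34.0)
    censor_at: float = 35.0
    seed: int = 0
    # two-species mode
    conserved_fraction: float = 0.5
    n_conserved_de: int = 29
    discordant_count: int = 7
    human_group_sizes: tuple[int, int] = (36, 110)  # MNA, non-MNA

    def validate(self) -> None:
        if self.n_de_up + self.n_de_down > self.n_mirnas:
            raise ValueError("planted DE count exceeds number of miRNAs")
        if not np.isfinite(self.effect_log2fc):
            raise ValueError("effect size must be finite")
        if min(self.group_sizes) < 1:
            raise ValueError("both groups need at least one sample")
        if not 0.0 <= self.conserved_fraction <= 1.0:
            raise ValueError("conserved_fraction must lie in [0, 1]")


@dataclass
class TruthTable:
    """Planted ground truth for a synthetic run.

    ``mirna`` has one row per miRNA: direction in {Up, Down, Null}, true
    log2 fold change, and in two-species mode a conserved flag plus the
    planted human direction.  ``sample_shift`` records each sample's true
    global Ct shift.
    """

    mirna: pd.DataFrame
    sample_shift: pd.Series

    @property
    def planted_de(self) -> pd.Index:
        return self.mirna.index[self.mirna["direction"] != "Null"]


def _species_frame(
    prefix: str,
    n_mirnas: int,
) -> pd.Index:
    width = len(str(n_mirnas))
    return pd.Index(
        [f"{prefix}-syn-mir-{i + 1:0{width}d}" for i in range(n_mirnas)], name="mirna"
    )


def _simulate(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    mirnas: pd.Index,
    directions: pd.Series,
    group_sizes: tuple[int, int],
    group_labels: tuple[str, str],
    sample_prefixes: tuple[str, str],
    species: str,
) -> tuple[CtMatrix, pd.Series]:
    n1, n2 = group_sizes
    n_samples = n1 + n2
    sample_ids = [f"{sample_prefixes[0]}{i + 1:02d}" for i in range(n1)] + [
        f"{sample_prefixes[1]}{i + 1:02d}" for i in range(n2)
    ]
    baseline = rng.uniform(*spec.baseline_range, size=len(mirnas))
    shift = rng.normal(0.0, spec.sample_shift_sd, size=n_samples)
    noise = rng.normal(0.0, spec.sigma_ct, size=(len(mirnas), n_samples))

    # Up = over-expressed in group 1 = lower Ct there (1 cycle per log2 unit)
    ct_effect = np.where(
        directions.to_numpy() == "Up", -spec.effect_log2fc,
        np.where(directions.to_numpy() == "Down", spec.effect_log2fc, 0.0),
    )
    in_group1 = np.array([1.0] * n1 + [0.0] * n2)
    ct = baseline[:, None] + ct_effect[:, None] * in_group1[None, :] + shift[None, :] + noise

    detected = ct <= spec.censor_at
    values = np.where(detected, ct, np.nan)  # censored entries report Undetermined
    meta = pd.DataFrame(
        {
            "species": species,
            "tissue_class": [group_labels[0]] * n1 + [group_labels[1]] * n2,
            "genotype": [group_labels[0]] * n1 + [group_labels[1]] * n2,
            "study": "synthetic",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    m = CtMatrix(
        values=pd.DataFrame(values, index=mirnas, columns=sample_ids),
        detected=pd.DataFrame(detected, index=mirnas, columns=sample_ids),
        samples=meta,
    )
    return m, pd.Series(shift, index=sample_ids, name="true_shift")


def _plant_directions(
    spec: SyntheticSpec, rng: np.random.Generator, mirnas: pd.Index
) -> pd.Series:
    directions = pd.Series("Null", index=mirnas, dtype=object)
    de_idx = rng.choice(len(mirnas), size=spec.n_de_up + spec.n_de_down, replace=False)
    directions.iloc[de_idx[: spec.n_de_up]] = "Up"
    directions.iloc[de_idx[spec.n_de_up :]] = "Down"
    return directions


def simulate_ct_matrix(spec: SyntheticSpec) -> tuple[CtMatrix, TruthTable]:
    """Generate one two-class Ct matrix plus its ground truth.

    Ct_ij = baseline_i - effect_i * [j in tumor group] + shift_j + eps_ij
    with eps ~ Normal(0, sigma_ct); entries above the censoring limit are
    marked Undetermined.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mirnas = _species_frame("mmu", spec.n_mirnas)
    directions = _plant_directions(spec, rng, mirnas)
    m, shift = _simulate(
        spec, rng, mirnas, directions, spec.group_sizes,
        ("tumor", "adrenal"), ("T", "A"), "mouse",
    )
    lfc = np.where(directions == "Up", spec.effect_log2fc,
                   np.where(directions == "Down", -spec.effect_log2fc, 0.0))
    truth = TruthTable(
        mirna=pd.DataFrame({"direction": directions, "true_log2fc": lfc}, index=mirnas),
        sample_shift=shift,
    )
    return m, truth


def _random_sequences(rng: np.random.Generator, n: int, length: int = 22) -> list[str]:
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        s = "".join(rng.choice(_RNA, size=length))
        if s not in seqs:
            seqs.add(s)
            out.append(s)
    return out


def simulate_two_species(
    spec: SyntheticSpec,
) -> tuple[CtMatrix, CtMatrix, str, TruthTable]:
    """Generate paired mouse and human cohorts with a planted concordance split.

    A ``conserved_fraction`` of miRNAs receive identical synthetic mature
    sequences in both species (all other sequences are unique, so the
    exact-identity homology map recovers exactly the planted conserved
    set).  ``n_conserved_de`` mouse-DE miRNAs fall in the conserved set;
    ``discordant_count`` of those are flipped in direction in the human
    cohort, the rest planted concordantly.  Returns (mouse CtMatrix, human
    CtMatrix, mature-FASTA text for both species, truth).
    """
    spec.validate()
    if spec.discordant_count > spec.n_conserved_de:
        raise ValueError("discordant_count exceeds planted conserved DE count")
    if spec.n_conserved_de > spec.n_de_up + spec.n_de_down:
        raise ValueError("n_conserved_de exceeds planted DE count")
    n_conserved = int(round(spec.conserved_fraction * spec.n_mirnas))
    if spec.n_conserved_de > n_conserved:
        raise ValueError("n_conserved_de exceeds the conserved set size")

    rng = np.random.default_rng(spec.seed)
    mouse_names = _species_frame("mmu", spec.n_mirnas)
    human_names = pd.Index(
        [n.replace("mmu-", "hsa-", 1) for n in mouse_names], name="mirna"
    )

    directions = _plant_directions(spec, rng, mouse_names)
    de_positions = np.flatnonzero(directions != "Null")
    null_positions = np.flatnonzero(directions == "Null")

    # conserved set: n_conserved_de of the DE miRNAs + nulls to fill the quota
    conserved_de = rng.choice(de_positions, size=spec.n_conserved_de, replace=False)
    n_null_conserved = n_conserved - spec.n_conserved_de
    conserved_null = rng.choice(null_positions, size=n_null_conserved, replace=False)
    conserved = np.zeros(spec.n_mirnas, dtype=bool)
    conserved[conserved_de] = True
    conserved[conserved_null] = True

    # human directions: copy mouse over conserved DE, flip the discordant subset
    human_dir = pd.Series("Null", index=mouse_names, dtype=object)
    human_dir.iloc[conserved_de] = directions.iloc[conserved_de]
    flipped = rng.choice(conserved_de, size=spec.discordant_count, replace=False)
    flip = {"Up": "Down", "Down": "Up"}
    human_dir.iloc[flipped] = [flip[d] for d in directions.iloc[flipped]]

    mouse_m, mouse_shift = _simulate(
        spec, rng, mouse_names, directions, spec.group_sizes,
        ("tumor", "adrenal"), ("T", "A"), "mouse",
    )
    human_dir_named = pd.Series(human_dir.to_numpy(), index=human_names)
    human_m, _ = _simulate(
        spec, rng, human_names, human_dir_named, spec.human_group_sizes,
        ("MNA", "non-MNA"), ("H", "N"), "human",
    )

    # mature sequences: identical for conserved pairs, globally unique otherwise
    n_unique = spec.n_mirnas + int((~conserved).sum())
    pool = _random_sequences(rng, n_unique)
    mouse_seq = pool[: spec.n_mirnas]
    extra = iter(pool[spec.n_mirnas :])
    human_seq = [
        mouse_seq[i] if conserved[i] else next(extra) for i in range(spec.n_mirnas)
    ]
    fasta_lines = []
    for i, name in enumerate(mouse_names):
        fasta_lines.append(f">{name} SYNMIMAT{i:05d}\n{mouse_seq[i]}")
    for i, name in enumerate(human_names):
        fasta_lines.append(f">{name} SYNMIMAT{i + spec.n_mirnas:05d}\n{human_seq[i]}")
    fasta = "\n".join(fasta_lines) + "\n"

    lfc = np.where(directions == "Up", spec.effect_log2fc,
                   np.where(directions == "Down", -spec.effect_log2fc, 0.0))
    truth = TruthTable(
        mirna=pd.DataFrame(
            {
                "direction": directions,
                "true_log2fc": lfc,
                "conserved": conserved,
                "human_direction": human_dir.to_numpy(),
            },
            index=mouse_names,
        ),
        sample_shift=mouse_shift,
    )
    return mouse_m, human_m, fasta, truth


def evaluate_against_truth(
    results: Sequence[DEResult], truth: TruthTable
) -> dict[str, float]:
    """Score DE calls against planted truth: sensitivity, FDR, direction accuracy.

    sensitivity = recovered planted DE / planted DE; FDR = false calls /
    all calls (0 when nothing is called); direction accuracy = fraction of
    correctly recovered planted miRNAs whose called direction matches the
    planted one.
    """
    truth_dir = truth.mirna["direction"]
    called = {r.mirna: r.direction for r in results}
    unknown = [m for m in called if m not in truth_dir.index]
    if unknown:
        raise ValueError(f"results contain miRNAs absent from truth: {unknown[:5]}")

    planted = set(truth.planted_de)
    de_calls = {m for m, d in called.items() if d != "NS"}
    tp = de_calls & planted
    fp = de_calls - planted
    sensitivity = len(tp) / len(planted) if planted else float("nan")
    fdr = len(fp) / len(de_calls) if de_calls else 0.0
    dir_ok = sum(1 for m in tp if called[m] == truth_dir[m])
    direction_accuracy = dir_ok / len(tp) if tp else float("nan")
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "direction_accuracy": direction_accuracy,
        "n_true_positive": float(len(tp)),
        "n_false_positive": float(len(fp)),
    }
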