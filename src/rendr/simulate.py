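"""Synthetic data with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised without any external data:

* synthetic reference sequences (ribozyme, CDS with a uracil-initial codon
  at position 66, RNA inputs) — arbitrary-composition stand-ins generated
  from a seed, *not* the natural sequences;
* a split-site library ground truth (Dirichlet-skewed proportions, planted
  functional sites with high on-state activity);
* a three-round sort: per-cell fluorescence is lognormal around each
  site's activity for the round's condition, and gates retain the top/
  bottom fraction of the mixed population (top 14% / bottom 85% / top 14%
  by default, matching a high-on, low-off selection);
* amplicon reads spanning the 5'-fragment/guide junction with iid
  substitution errors, written as Phred+33 FASTQ;
* plate FL/OD data generated from the ln-linear thermodynamic model with
  lognormal noise and an autofluorescence floor, decomposed into raw
  FL/OD with media-blank offsets so blank correction inverts exactly.

All generators are bit-reproducible given their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sequences import GuidePair, NucSeq, design_guides

__all__ = [
    "GateRound",
    "SimConfig",
    "LibraryGroundTruth",
    "SortResult",
    "synthetic_ribozyme",
    "synthetic_cds",
    "synthetic_input",
    "guide_length_panel",
    "simulate_split_library",
    "simulate_sort",
    "sequencing_counts",
    "simulate_reads",
    "simulate_plate_from_thermo",
]

_BASES = np.array(list("ACGU"))
_STOPS = {"UAA", "UAG", "UGA"}


def synthetic_ribozyme(length: int = 420, seed: int = 2023, name: str = "synthetic_ribozyme") -> NucSeq:
    """A synthetic ribozyme-length stand-in sequence (seeded, uniform bases).

    Length 420 gives the 419 internal split sites of the natural splicing
    ribozyme construct this emulates; the base composition is arbitrary.
    """
    rng = np.random.default_rng(seed)
    return NucSeq("".join(rng.choice(_BASES, size=length)), name=name)


def synthetic_cds(n_codons: int = 239, seed: int = 11, u_codon: int = 66) -> NucSeq:
    """A synthetic CDS stand-in with a U-initial codon at ``u_codon``.

    Starts with AUG, ends with a stop, avoids internal stops, and places
    UAU at codon ``u_codon`` so that the first nucleotide of that codon
    (CDS position ``3*(u_codon-1)+1``) is a valid ribozyme insertion site —
    emulating insertion within a tyrosine codon of a reporter CDS.
    """
    rng = np.random.default_rng(seed)
    codons = ["AUG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons[u_codon - 1] = "UAU"
    codons.append("UAA")
    return NucSeq("".join(codons), name="synthetic_cds")


def synthetic_input(length: int = 650, seed: int = 5, name: str = "synthetic_input") -> NucSeq:
    """A synthetic RNA-input transcript (seeded, uniform bases)."""
    rng = np.random.default_rng(seed)
    return NucSeq("".join(rng.choice(_BASES, size=length)), name=name)


def guide_length_panel(
    input_rna: NucSeq,
    total_lengths: tuple[int, ...] = (0, 82, 164, 246, 328, 650),
) -> list[tuple[int, GuidePair]]:
    """Guide pairs with varying total interaction length against one input.

    Each total length is split as evenly as possible between the two guides
    over adjacent windows starting at the input 5' end (length 0 is the
    no-guide control).  Mirrors a guide-length titration experiment.
    """
    panel = []
    for total in total_lengths:
        if total > len(input_rna):
            raise ValueError(f"total interaction {total} exceeds input length {len(input_rna)}")
        l1 = total // 2
        pair = design_guides(input_rna, (1, 1 + l1), (1 + l1, 1 + total))
        panel.append((total, pair))
    return panel


# ---------------------------------------------------------------------------
# library, sorting, sequencing


@dataclass(frozen=True)
class GateRound:
    """One sorting round: condition ('on'/'off'), gate side, gate fraction."""

    condition: str
    gate: str  # 'top' or 'bottom'
    fraction: float

    def __post_init__(self):
        if self.condition not in ("on", "off"):
            raise ValueError(f"condition must be 'on' or 'off', got {self.condition!r}")
        if self.gate not in ("top", "bottom"):
            raise ValueError(f"gate must be 'top' or 'bottom', got {self.gate!r}")
        if not (0 < self.fraction <= 1):
            raise ValueError(f"gate fraction {self.fraction} outside (0, 1]")


#: The default selection scheme: sort bright cells without inhibitor,
#: dim cells with inhibitor, then bright cells again.
DEFAULT_ROUNDS = (
    GateRound("on", "top", 0.14),
    GateRound("off", "bottom", 0.85),
    GateRound("on", "top", 0.14),
)


@dataclass
class SimConfig:
    """Knobs of the FACS-seq simulation."""

    n_cells: int = 200_000
    rounds: tuple[GateRound, ...] = DEFAULT_ROUNDS
    read_depth: int = 100_000
    read_len: int = 150
    error_rate: float = 0.005
    fluor_cv: float = 0.3  # lognormal CV of single-cell fluorescence
    seed: int | None = None

    def __post_init__(self):
        if self.n_cells <= 0 or self.read_depth <= 0 or self.read_len <= 0:
            raise ValueError("all counts must be positive")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error rate must be in [0, 1)")


@dataclass
class LibraryGroundTruth:
    """Per-split-site ground truth of a simulated insertion library."""

    proportions: np.ndarray     # library skew over sites, sums to 1
    on_activity: np.ndarray     # FL/OD-scale activity without inhibitor
    off_activity: np.ndarray    # FL/OD-scale activity with inhibitor
    functional: np.ndarray      # planted functional sites (bool)
    sites: np.ndarray           # split indices 1..L-1
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "split_index": self.sites,
                "proportion": self.proportions,
                "on_activity": self.on_activity,
                "off_activity": self.off_activity,
                "functional": self.functional,
            }
        )


def simulate_split_library(
    ribozyme_len: int = 420,
    skew: float = 1.0,
    n_functional: int = 20,
    seed: int | None = None,
    on_level: float = 30_000.0,
    off_level: float = 200.0,
    on_cv: float = 0.25,
) -> LibraryGroundTruth:
    """Ground truth for a transposon split-site library.

    ``skew = 0`` gives exactly uniform proportions over the L-1 sites;
    ``skew > 0`` draws them from a symmetric Dirichlet with concentration
    ``1/skew`` (larger skew -> more uneven library).  ``n_functional``
    sites drawn uniformly get a high on-state activity (lognormal around
    ``on_level``); all off-state activities sit at the autofluorescence
    level ``off_level``.
    """
    if ribozyme_len < 2:
        raise ValueError("ribozyme length must be >= 2")
    n_sites = ribozyme_len - 1
    rng = np.random.default_rng(seed)
    if skew == 0:
        proportions = np.full(n_sites, 1.0 / n_sites)
    else:
        proportions = rng.dirichlet(np.full(n_sites, 1.0 / skew))
    functional = np.zeros(n_sites, dtype=bool)
    functional[rng.choice(n_sites, size=n_functional, replace=False)] = True
    sigma = np.sqrt(np.log1p(on_cv**2))
    on = np.full(n_sites, off_level)
    on[functional] = on_level * np.exp(rng.normal(0.0, sigma, size=n_functional))
    off = np.full(n_sites, off_level)
    return LibraryGroundTruth(
        proportions, on, off, functional, np.arange(1, ribozyme_len), seed
    )


@dataclass
class SortResult:
    """Outcome of sequential sorting rounds over a library."""

    initial_counts: np.ndarray
    rounds: list[dict] = field(default_factory=list)

    @property
    def final_counts(self) -> np.ndarray:
        return self.rounds[-1]["retained"] if self.rounds else self.initial_counts

    @property
    def final_proportions(self) -> np.ndarray:
        c = self.final_counts
        return c / c.sum()


def _gate_threshold(mu: np.ndarray, weights: np.ndarray, sigma: float, round_spec: GateRound) -> float:
    """ln-fluorescence threshold putting ``fraction`` of the mixture in the gate."""
    lo, hi = mu.min() - 10 * sigma, mu.max() + 10 * sigma

    def below(t: float) -> float:
        return float(weights @ stats.norm.cdf((t - mu) / sigma))

    target = round_spec.fraction if round_spec.gate == "bottom" else 1 - round_spec.fraction
    if round_spec.fraction == 1.0:
        return lo if round_spec.gate == "top" else hi
    return optimize.brentq(lambda t: below(t) - target, lo, hi)


def simulate_sort(
    truth: LibraryGroundTruth,
    config: SimConfig,
    seed: int | None = None,
) -> SortResult:
    """Run the configured sorting rounds over the library.

    Each round: cells are drawn multinomially from the current pool
    proportions (growth between rounds as unbiased amplification), each
    cell's fluorescence is lognormal around its site's activity for the
    round's condition, and cells inside the gate are retained.  Retention
    is sampled per site as a binomial with the exact in-gate probability,
    so the population-level retained fraction matches the gate fraction up
    to sampling error.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sigma = float(np.sqrt(np.log1p(config.fluor_cv**2)))
    proportions = truth.proportions.copy()
    initial = rng.multinomial(config.n_cells, proportions)
    result = SortResult(initial_counts=initial)
    counts = initial
    for spec in config.rounds:
        if counts.sum() == 0:
            raise RuntimeError("pool extinct before sorting round")
        pool_p = counts / counts.sum()
        cells = rng.multinomial(config.n_cells, pool_p)
        activity = truth.on_activity if spec.condition == "on" else truth.off_activity
        mu = np.log(activity)
        present = cells > 0
        t = _gate_threshold(mu[present], cells[present] / cells.sum(), sigma, spec)
        z = (t - mu) / sigma
        p_keep = stats.norm.sf(z) if spec.gate == "top" else stats.norm.cdf(z)
        retained = rng.binomial(cells, p_keep)
        if retained.sum() == 0:
            raise RuntimeError(f"empty gate in round {spec}")
        result.rounds.append(
            {
                "spec": spec,
                "cells": cells,
                "retained": retained,
                "threshold_ln_fl": t,
                "realized_fraction": retained.sum() / cells.sum(),
            }
        )
        counts = retained
    return result


def sequencing_counts(proportions: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Per-site read counts: multinomial sequencing of a pool at ``depth``."""
    return rng.multinomial(depth, np.asarray(proportions) / np.sum(proportions))


# ---------------------------------------------------------------------------
# reads


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * np.log10(error_rate))))
    return chr(33 + q)


def simulate_reads(
    site_counts,
    ribozyme: NucSeq | str,
    guide1: NucSeq | str,
    upstream: str = "",
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int | None = None,
    path: str | Path | None = None,
):
    """Amplicon reads spanning the 5'-fragment/guide junction per site.

    ``site_counts`` maps split index -> read count (dict, Series, or array
    over sites 1..L-1).  Each read is a ``read_len`` window of the amplicon
    ``upstream + ribozyme[1..s] + guide1`` positioned so the junction sits
    near the read centre, with iid substitution errors at ``error_rate``
    and constant Phred+33 qualities consistent with that rate.  Writes
    FASTQ to ``path`` if given, else returns the records; the number of
    reads emitted always equals the number requested.
    """
    rib, g1 = str(ribozyme), str(guide1)
    if isinstance(site_counts, dict):
        items = sorted(site_counts.items())
    elif isinstance(site_counts, pd.Series):
        items = list(site_counts.items())
    else:
        items = list(enumerate(np.asarray(site_counts), start=1))
    rng = np.random.default_rng(seed)
    qchar = _phred_char(error_rate)
    records = []
    for s, n in items:
        n = int(n)
        if n == 0:
            continue
        if not (1 <= s <= len(rib) - 1):
            raise ValueError(f"split index {s} out of range")
        amplicon = upstream + rib[:s] + g1
        junction = len(upstream) + s
        start = min(max(0, junction - read_len // 2), max(0, len(amplicon) - read_len))
        template = amplicon[start : start + read_len]
        for i in range(n):
            seq = template
            if error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                errs = np.flatnonzero(rng.random(len(seq)) < error_rate)
                for e in errs:
                    cur = arr[e].decode()
                    alt = [b for b in "ACGU" if b != cur]
                    arr[e] = alt[int(rng.integers(3))].encode()
                seq = arr.tobytes().decode()
            records.append((f"site{s}_read{i}", seq, qchar * len(seq)))
    if path is not None:
        with open(path, "w") as fh:
            for rid, seq, qual in records:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        return Path(path)
    return records


# ---------------------------------------------------------------------------
# plates


def simulate_plate_from_thermo(
    designs: pd.DataFrame,
    a: float = np.log(200.0),
    b: float = 0.008,
    sigma: float = 0.4,
    floor: float = 200.0,
    seed: int | None = None,
    n_replicates: int = 4,
    od_true: float = 0.5,
    blank_fl: float = 100.0,
    blank_od: float = 0.05,
    n_media_blanks: int = 4,
) -> pd.DataFrame:
    """Plate FL/OD generated from the ln-linear thermodynamic model.

    Each design (rows with ``design_id`` and ``dg_predicted``) gets
    ``n_replicates`` wells with true expression
    ``FL/OD = exp(a + b * dG_Predicted + N(0, sigma^2))`` floored at the
    autofluorescence ``floor`` (floored wells flagged).  Raw FL and OD are
    reconstructed with media-blank offsets so that blank correction
    inverts the decomposition exactly at ``sigma = 0``.  Media-blank and
    blank-cell (autofluorescence) control wells are appended.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for _, d in designs.iterrows():
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            fl_od = float(np.exp(a + b * d["dg_predicted"] + noise))
            floored = fl_od <= floor
            fl_od = max(fl_od, floor)
            rows.append(
                {
                    "well": f"W{well:03d}",
                    "design_id": d["design_id"],
                    "condition": "+input",
                    "replicate": rep,
                    "FL": fl_od * od_true + blank_fl,
                    "OD": od_true + blank_od,
                    "is_media_blank": False,
                    "is_blank_cells": False,
                    "floored": floored,
                }
            )
            well += 1
    for rep in range(1, n_media_blanks + 1):
        rows.append(
            {
                "well": f"W{well:03d}",
                "design_id": "media_blank",
                "condition": "+input",
                "replicate": rep,
                "FL": blank_fl,
                "OD": blank_od,
                "is_media_blank": True,
                "is_blank_cells": False,
                "floored": False,
            }
        )
        well += 1
    for rep in range(1, n_replicates + 1):
        rows.append(
            {
                "well": f"W{well:03d}",
                "design_id": "blank_cells",
                "condition": "+input",
                "replicate": rep,
                "FL": floor * od_true + blank_fl,
                "OD": od_true + blank_od,
                "is_media_blank": False,
                "is_blank_cells": True,
                "floored": True,
            }
        )
        well += 1
    return pd.DataFrame(rows)
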