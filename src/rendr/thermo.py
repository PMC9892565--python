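"""Thermodynamic expression model for split-ribozyme RNA sensors.

The sensor's output is assumed to be limited by hybridisation of the two
RNA guides with the RNA input.  Two states are compared: the *initial
state* (IS), in which the guides and the input are folded independently,
and the *extended duplex* (ED), in which both guides are fully hybridised
to their windows on the input.  The model predictor is the free-energy
difference

    dG_Predicted = dG_guide1 + dG_guide2 + dG_input - dG_ED   [kcal/mol]

and the natural log of observed expression (FL/OD) is modelled as linear
in dG_Predicted.  Only the guides and the input enter the energy
calculation; the ribozyme fragment cores are excluded.

Energies come from a pluggable :class:`EnergyBackend`:

* :class:`NearestNeighborBackend` — a self-contained Watson-Crick
  nearest-neighbour model (stack table shipped as TSV) with a single-hairpin
  monomer folder; no external software, used for property checks.
* :class:`ViennaRNABackend` — adapter over the ViennaRNA python bindings
  (full secondary-structure MFE, Turner parameters) for quantitative work.

The ln-linear model itself is exposed statsmodels-style:
``ExpressionModel(dg, fl_od).fit()`` returns an
:class:`ExpressionModelResults` with estimates, standard errors, R² and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sequences import GuidePair, NucSeq

__all__ = [
    "EnergyBackend",
    "NearestNeighborBackend",
    "ViennaRNABackend",
    "get_backend",
    "ThermoStates",
    "load_nn_params",
    "nn_duplex_energy",
    "dg_initial_state",
    "dg_extended_duplex",
    "dg_predicted",
    "compute_thermo_states",
    "ExpressionModel",
    "ExpressionModelResults",
    "fit_expression_model",
]

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_RT37 = 0.0019872 * 310.15  # kcal/mol


def load_nn_params() -> dict:
    """Load the nearest-neighbour parameter table shipped with the package.

    Returns a dict with ``stack`` (top-strand dinucleotide -> kcal/mol),
    ``init`` (duplex initiation), ``terminal_au`` (per helix end closed by
    an A-U pair) and ``hairpin`` (loop size -> initiation penalty).
    """
    path = resources.files("rendr.data").joinpath("nn_params.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    stacks = {r.key: float(r.dg37) for r in df[df.kind == "stack"].itertuples()}
    init = df[(df.kind == "init") & (df.key == "duplex")].dg37.iloc[0]
    term_au = df[(df.kind == "init") & (df.key == "terminal_au")].dg37.iloc[0]
    hairpin = {int(r.key): float(r.dg37) for r in df[df.kind == "hairpin"].itertuples()}
    return {
        "stack": stacks,
        "init": float(init),
        "terminal_au": float(term_au),
        "hairpin": hairpin,
    }


def _hairpin_penalty(loop: int, table: dict[int, float]) -> float:
    if loop in table:
        return table[loop]
    nmax = max(table)
    return table[nmax] + 1.75 * _RT37 * math.log(loop / nmax)


def nn_duplex_energy(
    a: str | NucSeq,
    b: str | NucSeq,
    paired: Sequence[bool] | None = None,
    params: dict | None = None,
) -> float:
    """Nearest-neighbour free energy of an antiparallel duplex, kcal/mol.

    ``a`` and ``b`` are equal-length strands given 5'->3'; position ``i`` of
    ``a`` faces position ``n-1-i`` of ``b``.  ``paired`` optionally marks
    which positions of ``a`` are paired (defaults to Watson-Crick
    complementarity of the facing bases).  Each maximal run of consecutive
    pairs contributes its stack sum plus one duplex-initiation penalty and
    terminal A-U penalties; mismatches break stacks, so the energy is
    additive over mismatch-separated helix blocks.  No pairs -> 0.
    """
    p = params or load_nn_params()
    sa, sb = str(a), str(b)
    if len(sa) != len(sb):
        raise ValueError(f"strand lengths differ: {len(sa)} vs {len(sb)}")
    n = len(sa)
    if paired is None:
        paired = [(sa[i], sb[n - 1 - i]) in _WC for i in range(n)]
    else:
        paired = [bool(paired[i]) and (sa[i], sb[n - 1 - i]) in _WC for i in range(n)]
    energy = 0.0
    i = 0
    while i < n:
        if not paired[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and paired[j + 1]:
            j += 1
        # helix block a[i..j]
        energy += p["init"]
        for k in range(i, j):
            energy += p["stack"][sa[k : k + 2]]
        for end in {i, j}:  # a one-pair block has a single end
            if {sa[end], sb[n - 1 - end]} == {"A", "U"}:
                energy += p["terminal_au"]
        i = j + 1
    return energy


@runtime_checkable
class EnergyBackend(Protocol):
    """Contract for free-energy engines (37 C, deterministic).

    ``mfe`` returns the monomer minimum-free-energy in kcal/mol (<= 0, with
    0 for empty or unpairable sequences).  ``mfe_constrained`` is the same
    with a set of 1-based positions forced unpaired.  ``duplex_dg`` returns
    the energy of a guide fully hybridised to its window, with ``paired``
    marking which guide positions (0-based mask) form pairs.
    """

    name: str

    def mfe(self, seq: str) -> float: ...

    def mfe_constrained(self, seq: str, unpaired_positions: Iterable[int]) -> float: ...

    def duplex_dg(self, guide: str, window: str, paired: Sequence[bool]) -> float: ...


class NearestNeighborBackend:
    """Self-contained Watson-Crick nearest-neighbour energy model.

    Duplexes use the shipped stack/initiation table.  Monomer MFE is a
    single-hairpin approximation: the best single helix closing a loop of
    >= 3 nt, scored as stack sum plus hairpin-loop initiation (0 if nothing
    pairs).  That captures the hairpin-forming guides and unstructured
    controls the property suite exercises, while staying dependency-free.
    """

    name = "internal"

    def __init__(self, params: dict | None = None):
        self.params = params or load_nn_params()

    def mfe(self, seq: str) -> float:
        return self.mfe_constrained(seq, ())

    def mfe_constrained(self, seq: str, unpaired_positions: Iterable[int]) -> float:
        s = str(seq)
        n = len(s)
        blocked = {int(i) - 1 for i in unpaired_positions}  # to 0-based
        best = 0.0
        p = self.params
        for i in range(n):
            if i in blocked:
                continue
            for j in range(i + 4, n):
                if j in blocked or (s[i], s[j]) not in _WC:
                    continue
                # grow a helix inward from (i, j)
                stacks = 0.0
                k = 0
                while True:
                    loop = (j - k) - (i + k) - 1
                    if k > 0:
                        best = min(best, stacks + _hairpin_penalty(loop, p["hairpin"]))
                    ni, nj = i + k + 1, j - k - 1
                    if nj - ni - 1 < 3 or ni in blocked or nj in blocked:
                        break
                    if (s[ni], s[nj]) not in _WC:
                        break
                    stacks += p["stack"][s[i + k : i + k + 2]]
                    k += 1
        return best

    def duplex_dg(self, guide: str, window: str, paired: Sequence[bool]) -> float:
        if len(guide) == 0:
            return 0.0
        return nn_duplex_energy(guide, window, paired=paired, params=self.params)


class ViennaRNABackend:
    """Adapter over the ViennaRNA python bindings (Turner parameters).

    Monomer terms are full secondary-structure MFE folds; the constrained
    variants use hard constraints.  Duplex terms are evaluated on the
    two-strand complex with the designed pairing imposed, so the returned
    energy includes ViennaRNA's intermolecular initiation term.
    """

    name = "vienna"

    def __init__(self):
        import RNA  # deferred: optional dependency

        self._RNA = RNA

    def mfe(self, seq: str) -> float:
        return self.mfe_constrained(seq, ())

    def mfe_constrained(self, seq: str, unpaired_positions: Iterable[int]) -> float:
        s = str(seq)
        if len(s) == 0:
            return 0.0
        fc = self._RNA.fold_compound(s)
        for i in unpaired_positions:
            fc.hc_add_up(int(i))
        _, dg = fc.mfe()
        return float(dg)

    def duplex_dg(self, guide: str, window: str, paired: Sequence[bool]) -> float:
        g, w = str(guide), str(window)
        if len(g) == 0:
            return 0.0
        if len(g) != len(w):
            raise ValueError("guide/window length disagreement")
        n = len(g)
        if not any(paired):
            return 0.0
        left = "".join("(" if paired[i] else "." for i in range(n))
        right = "".join(")" if paired[n - 1 - j] else "." for j in range(n))
        fc = self._RNA.fold_compound(f"{g}&{w}")
        return float(fc.eval_structure(left + right))


def get_backend(name: str) -> EnergyBackend:
    """Resolve a backend by name: ``internal`` or ``vienna``/``external``."""
    if name == "internal":
        return NearestNeighborBackend()
    if name in ("vienna", "external"):
        return ViennaRNABackend()
    raise ValueError(f"unknown energy backend {name!r}")


# ---------------------------------------------------------------------------
# model states


@dataclass(frozen=True)
class ThermoStates:
    """The free-energy terms of the expression model, kcal/mol."""

    dg_guide1: float
    dg_guide2: float
    dg_input: float
    dg_ed: float

    @property
    def dg_predicted(self) -> float:
        return self.dg_guide1 + self.dg_guide2 + self.dg_input - self.dg_ed


def dg_initial_state(
    guides: GuidePair, input_rna: NucSeq, backend: EnergyBackend
) -> tuple[float, float, float]:
    """IS terms: each species folded alone (guides and input only)."""
    return (
        backend.mfe(guides.guide1.residues),
        backend.mfe(guides.guide2.residues),
        backend.mfe(input_rna.residues),
    )


def _paired_mask(guide: NucSeq, window: str, mismatches: tuple[int, ...]) -> list[bool]:
    n = len(guide)
    mism = set(mismatches)
    return [
        (i + 1) not in mism and (guide[i], window[n - 1 - i]) in _WC
        for i in range(n)
    ]


def dg_extended_duplex(guides: GuidePair, input_rna: NucSeq, backend: EnergyBackend) -> float:
    """ED free energy: both guides fully hybridised to their input windows.

    Every non-mismatch guide position is paired with its window position;
    declared mismatch positions stay unpaired.  Input regions outside the
    paired windows may still fold (constrained monomer MFE), so with
    zero-length guides the ED reduces to the input's own MFE.
    """
    dg = 0.0
    constrained: list[int] = []
    for which, guide, window in (
        (1, guides.guide1, guides.input_window1),
        (2, guides.guide2, guides.input_window2),
    ):
        if window[1] > len(input_rna) + 1:
            raise ValueError(f"window {window} outside input of length {len(input_rna)}")
        wseq = input_rna.slice1(*window)
        if len(wseq) != len(guide):
            raise ValueError(f"guide{which}/window length disagreement")
        if len(guide) == 0:
            continue
        paired = _paired_mask(guide, wseq, guides.mismatches_in(which))
        dg += backend.duplex_dg(guide.residues, wseq, paired)
        n = len(guide)
        # input positions actually paired (window is antiparallel to guide)
        constrained.extend(
            window[0] + (n - 1 - i) for i in range(n) if paired[i]
        )
    dg += backend.mfe_constrained(input_rna.residues, constrained)
    return dg


def dg_predicted(states: ThermoStates) -> float:
    """The model predictor: IS energy sum minus ED energy."""
    return states.dg_predicted


def compute_thermo_states(
    guides: GuidePair, input_rna: NucSeq, backend: EnergyBackend
) -> ThermoStates:
    """Convenience: all four energy terms for one design."""
    g1, g2, gin = dg_initial_state(guides, input_rna, backend)
    ed = dg_extended_duplex(guides, input_rna, backend)
    return ThermoStates(g1, g2, gin, ed)


# ---------------------------------------------------------------------------
# ln-linear expression model


class ExpressionModel:
    """ln(FL/OD) ~ intercept + slope * dG_Predicted, fitted by OLS.

    Parameters
    ----------
    dg_predicted : array-like
        Model predictor per design, kcal/mol.
    fl_od : array-like
        Blank-corrected expression (FL/OD) per design; must be positive
        unless a ``floor`` is given.
    design_ids : sequence, optional
        Labels carried through to the results.
    floor : float, optional
        Autofluorescence floor.  Values at or below it are floored there
        before taking ln and flagged; floored points are excluded from the
        fit by default (they carry no expression information).
    exclude_floored : bool
        Drop floored points from the fit (default True).
    """

    def __init__(
        self,
        dg_predicted,
        fl_od,
        design_ids: Sequence | None = None,
        floor: float | None = None,
        exclude_floored: bool = True,
    ):
        dg = np.asarray(dg_predicted, dtype=float)
        y = np.asarray(fl_od, dtype=float)
        if dg.shape != y.shape or dg.ndim != 1:
            raise ValueError("dg_predicted and fl_od must be equal-length 1-d arrays")
        if design_ids is None:
            design_ids = [f"design_{i}" for i in range(len(dg))]
        floored = np.zeros(len(dg), dtype=bool)
        if floor is not None:
            if floor <= 0:
                raise ValueError("floor must be positive")
            floored = y <= floor
            y = np.maximum(y, floor)
        elif np.any(y <= 0):
            raise ValueError("fl_od must be positive (or provide an autofluorescence floor)")
        self.dg = dg
        self.fl_od = y
        self.design_ids = list(design_ids)
        self.floor = floor
        self.floored = floored
        self.exclude_floored = exclude_floored

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x: str = "dg_predicted",
        y: str = "fl_od",
        design_id: str | None = "design_id",
        **kwargs,
    ) -> "ExpressionModel":
        ids = df[design_id] if design_id and design_id in df.columns else None
        return cls(df[x].to_numpy(), df[y].to_numpy(), design_ids=ids, **kwargs)

    def fit(self) -> "ExpressionModelResults":
        use = ~self.floored if self.exclude_floored else np.ones(len(self.dg), bool)
        x, y = self.dg[use], np.log(self.fl_od[use])
        if len(x) < 3:
            raise ValueError(f"need >= 3 points to fit, got {len(x)}")
        if np.ptp(x) == 0:
            raise ValueError("all dg_predicted values identical: slope undefined")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        return ExpressionModelResults(self, res, use)


class ExpressionModelResults:
    """Fitted ln-linear expression model: estimates, uncertainty, R²."""

    def __init__(self, model: ExpressionModel, sm_results, used_mask: np.ndarray):
        self.model = model
        self.sm_results = sm_results
        self.used_mask = used_mask
        self.intercept, self.slope = (float(v) for v in sm_results.params)
        self.intercept_se, self.slope_se = (float(v) for v in sm_results.bse)
        self.rsquared = float(sm_results.rsquared)
        self.nobs = int(sm_results.nobs)

    r2 = property(lambda self: self.rsquared)

    def predict(self, dg) -> np.ndarray:
        """Predicted ln(FL/OD) at the given dG_Predicted values."""
        return self.intercept + self.slope * np.asarray(dg, dtype=float)

    @property
    def residuals(self) -> pd.Series:
        ids = [d for d, u in zip(self.model.design_ids, self.used_mask) if u]
        return pd.Series(np.asarray(self.sm_results.resid), index=ids, name="residual")

    def to_frame(self) -> pd.DataFrame:
        """Per-design table: dG, ln FL/OD, fitted value, residual, flags."""
        m = self.model
        ln_y = np.log(m.fl_od)
        fitted = self.predict(m.dg)
        return pd.DataFrame(
            {
                "design_id": m.design_ids,
                "dg_predicted": m.dg,
                "fl_od": m.fl_od,
                "ln_fl_od": ln_y,
                "fitted_ln_fl_od": fitted,
                "residual": ln_y - fitted,
                "floored": m.floored,
                "used_in_fit": self.used_mask,
            }
        )

    def summary(self) -> str:
        lines = [
            "ln-linear expression model: ln(FL/OD) = a + b * dG_Predicted",
            f"  n (fit)     : {self.nobs}",
            f"  slope b     : {self.slope:+.5f} +/- {self.slope_se:.5f}  [1/(kcal/mol)]",
            f"  intercept a : {self.intercept:+.4f} +/- {self.intercept_se:.4f}  [ln FL/OD]",
            f"  R^2         : {self.rsquared:.4f}",
        ]
        if self.model.floor is not None:
            n_floor = int(self.model.floored.sum())
            lines.append(
                f"  floored pts : {n_floor} at autofluorescence {self.model.floor:g}"
                f" ({'excluded' if self.model.exclude_floored else 'included'})"
            )
        return "\n".join(lines)


def fit_expression_model(points: Iterable[tuple[float, float]], **kwargs) -> ExpressionModelResults:
    """OLS of ln(FL/OD) on dG_Predicted for (dg, fl_od) pairs."""
    pts = list(points)
    dg = [p[0] for p in pts]
    y = [p[1] for p in pts]
    return ExpressionModel(dg, y, **kwargs).fit()
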