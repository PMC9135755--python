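"""Trade-off detection with allometric controls, and ratio-bias diagnostics.

An allocation trade-off between two structures predicts a *negative*
association between them once overall size is removed. Two complementary
constructions test this:

* :func:`conditional_association` — multiple regression of one focal trait
  on the other plus an allometric control (``A ~ size + B``); the partial
  coefficient on the partner trait is the trade-off test.
* :func:`residual_association` — regress each focal trait on the control,
  then regress the residual vectors on each other (the two-stage,
  plottable version of the same question).

Trait *ratios* (A/B) are a popular but biased alternative: whenever the
numerator scales non-isometrically the ratio retains size-driven signal,
manufacturing trade-off-like patterns where none exist.
:func:`ratio_size_test` measures that retained signal and
:func:`ratio_scenarios` decomposes how three very different allocation
histories produce identical ratios.

At the intraspecific level, :func:`classify_shifts` compares the pairwise
elevation-shift matrices of two structures: a trade-off predicts shifts of
opposite sign (inverse) pair by pair, with shifts below a minimum magnitude
(default 0.1 log units) set aside as minor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .pgls import LinearFit, ols_fit, pgls_fit
from .sma import PairwiseShiftMatrix
from .traits import TraitTable

logger = logging.getLogger(__name__)

__all__ = ["conditional_association", "residual_association",
           "classify_shifts", "ShiftClassification", "ratio_scenarios",
           "ratio_size_test", "elevation_diff_correlation", "TradeoffReport"]


def _fit(table, response, predictors, engine, cov=None, species_fixed=False,
         lambda_mode="ml"):
    if engine == "ols":
        return ols_fit(table, response, predictors,
                       species_fixed=species_fixed)
    if engine == "pgls":
        if cov is None:
            raise ValueError("engine='pgls' requires a phylogenetic "
                             "covariance (cov=...)")
        if species_fixed:
            raise ValueError("species fixed effects are not meaningful in a "
                             "species-level phylogenetic fit")
        return pgls_fit(table, response, predictors, cov,
                        lambda_mode=lambda_mode)
    raise ValueError(f"unknown engine {engine!r}")


def conditional_association(table, focal_y, focal_x, control, engine="ols",
                            cov=None, species_fixed=False,
                            lambda_mode="ml") -> LinearFit:
    """Partial association of ``focal_y`` with ``focal_x`` given ``control``.

    Fits ``focal_y ~ control + focal_x`` (plus species dummies when
    ``species_fixed``). A significantly negative ``focal_x`` coefficient is
    the signature consistent with an allocation trade-off.
    """
    return _fit(table, focal_y, [control, focal_x], engine, cov=cov,
                species_fixed=species_fixed, lambda_mode=lambda_mode)


def residual_association(table, trait_a, trait_b, control, engine="ols",
                         cov=None, lambda_mode="ml") -> LinearFit:
    """Two-stage residual test: A ~ control, B ~ control, then resA ~ resB.

    Each focal trait is regressed on the allometric control with the chosen
    engine; the ordinary residuals are then regressed on each other with
    the same engine. Returns the second-stage fit (slope on the partner
    residuals is the statistic of interest).
    """
    fit_a = _fit(table, trait_a, [control], engine, cov=cov,
                 lambda_mode=lambda_mode)
    fit_b = _fit(table, trait_b, [control], engine, cov=cov,
                 lambda_mode=lambda_mode)
    common = fit_a.resid.index.intersection(fit_b.resid.index)
    resid = pd.DataFrame({
        "species": common,
        f"resid_{trait_a}": fit_a.resid.loc[common].values,
        f"resid_{trait_b}": fit_b.resid.loc[common].values,
    }, index=pd.Index(common, name="observation_id"))
    rtab = TraitTable(resid, species_col="species",
                      log_cols=(f"resid_{trait_a}", f"resid_{trait_b}"),
                      log_base=table.log_base)
    return _fit(rtab, f"resid_{trait_a}", [f"resid_{trait_b}"], engine,
                cov=cov, lambda_mode=lambda_mode)


# ---------------------------------------------------------------------------
# pairwise shift classification
# ---------------------------------------------------------------------------

@dataclass
class ShiftClassification:
    """Per-pair trade-off classification of two structures' shift matrices."""
    pairs: pd.DataFrame          # group_i, group_j, delta/W/p per structure,
                                 # label, label_strict
    min_shift: float
    alpha: float
    n_pairs: int
    n_inverse: int               # default rule: opposite signs, both >= min
    n_inverse_strict: int        # additionally both pairwise p < alpha
    n_inverse_sign_first: int    # sign check before the minor exclusion
    counts: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Pairwise shift classification "
                 f"(min shift {self.min_shift}, alpha {self.alpha})"]
        lines.append(f"  inverse: {self.n_inverse} of {self.n_pairs} "
                     f"(strict: {self.n_inverse_strict}; sign-first order: "
                     f"{self.n_inverse_sign_first})")
        for label, n in sorted(self.counts.items()):
            lines.append(f"  {label}: {n}")
        return "\n".join(lines)


def _classify_pair(dA, dB, pA, pB, min_shift, alpha, strict):
    both_large = abs(dA) >= min_shift and abs(dB) >= min_shift
    opposite = dA * dB < 0
    sigA, sigB = pA < alpha, pB < alpha
    if opposite and both_large and (not strict or (sigA and sigB)):
        return "inverse"
    if sigA != sigB:
        return "single_structure"
    if abs(dA) < min_shift or abs(dB) < min_shift:
        return "minor"
    if dA * dB > 0:
        return "same_direction"
    return "none"


def classify_shifts(pair_a: PairwiseShiftMatrix, pair_b: PairwiseShiftMatrix,
                    min_shift: float = 0.1, alpha: float = 0.05,
                    strict: bool = False) -> ShiftClassification:
    """Classify every species pair by the joint direction of its shifts.

    For structures A and B with matched pairwise elevation-shift matrices,
    each pair gets exactly one label:

    * ``inverse`` — shifts of opposite sign in A and B, both at least
      ``min_shift`` in magnitude (with ``strict=True``, additionally both
      pairwise Wald p values below ``alpha``) — the trade-off signature;
    * ``single_structure`` — exactly one structure's pairwise test
      significant (the other minor or non-significant);
    * ``minor`` — |delta| below ``min_shift`` in either structure, with
      neither test singly significant;
    * ``same_direction`` — both shifts substantial and sharing a sign;
    * ``none`` — anything left.

    Counts under the default rule, the strict rule, and with the
    minor-shift exclusion applied after the sign check are all reported.
    """
    if list(pair_a.groups) != list(pair_b.groups):
        raise ValueError("shift matrices cover different group sets: "
                         f"{pair_a.groups} vs {pair_b.groups}")
    rows = []
    for i, j in pair_a.pair_index():
        dA, dB = pair_a.delta_elevation[i, j], pair_b.delta_elevation[i, j]
        pA, pB = pair_a.p[i, j], pair_b.p[i, j]
        label = _classify_pair(dA, dB, pA, pB, min_shift, alpha, strict)
        label_strict = _classify_pair(dA, dB, pA, pB, min_shift, alpha, True)
        rows.append({
            "group_i": pair_a.groups[i], "group_j": pair_a.groups[j],
            "delta_A": dA, "delta_B": dB, "W_A": pair_a.W[i, j],
            "W_B": pair_b.W[i, j], "p_A": pA, "p_B": pB,
            "label": label, "label_strict": label_strict,
        })
    pairs = pd.DataFrame(rows)
    n_pairs = len(pairs)
    n_inverse = int((pairs["label"] == "inverse").sum())
    n_strict = int((pairs["label_strict"] == "inverse").sum())
    # alternate order: sign first, then drop minor pairs from the tally
    sign_first = ((pairs["delta_A"] * pairs["delta_B"] < 0)
                  & (pairs["delta_A"].abs() >= min_shift)
                  & (pairs["delta_B"].abs() >= min_shift))
    if strict:
        sign_first &= (pairs["p_A"] < alpha) & (pairs["p_B"] < alpha)
    n_sign_first = int(sign_first.sum())
    if n_sign_first != n_inverse:
        logger.info("minor-exclusion order changes the inverse count: "
                    "%d vs %d", n_inverse, n_sign_first)
    counts = pairs["label"].value_counts().to_dict()
    return ShiftClassification(pairs, min_shift, alpha, n_pairs, n_inverse,
                               n_strict, n_sign_first, counts)


# ---------------------------------------------------------------------------
# ratio diagnostics
# ---------------------------------------------------------------------------

def ratio_scenarios(e0: float, f0: float, target_ratio: float,
                    split: float = 0.5) -> dict:
    """Three allocation histories producing the same trait ratio.

    Starting from raw trait values ``(e0, f0)`` with ratio ``e0/f0``, each
    scenario reaches ``target_ratio`` exactly:

    1. ``tradeoff`` — the numerator grows while the denominator shrinks,
       the change split in log space by ``split`` (default: equally,
       ``e0 * k**split, f0 / k**(1-split)`` with
       ``k = target_ratio / (e0/f0)``);
    2. ``numerator_increase`` — only the numerator changes;
    3. ``denominator_decrease`` — only the denominator changes.

    A ratio alone cannot distinguish the three.
    """
    if min(e0, f0, target_ratio) <= 0:
        raise ValueError("e0, f0 and target_ratio must be positive")
    k = target_ratio / (e0 / f0)
    scenarios = {
        "tradeoff": (e0 * k ** split, f0 / k ** (1.0 - split)),
        "numerator_increase": (e0 * k, f0),
        "denominator_decrease": (e0, f0 / k),
    }
    return scenarios


def ratio_size_test(table, numerator, denominator, against, engine="ols",
                    cov=None, lambda_mode="ml") -> LinearFit:
    """Does a trait ratio retain allometric (size-driven) signal?

    Computes ``ratio = numerator / denominator`` per row on the raw scale,
    then regresses log10(ratio) on the (log) ``against`` column. A
    significant coefficient means the ratio does not remove allometry —
    the bias mechanism that makes ratio-based trade-off inference
    unreliable under non-isometric scaling.
    """
    num = table.column(numerator).astype(float)
    den = table.column(denominator).astype(float)
    if table.is_logged(numerator) or table.is_logged(denominator):
        raise ValueError("ratio_size_test expects raw-scale numerator and "
                         "denominator columns")
    if (den == 0).any():
        row = den.index[den == 0][0]
        raise ZeroDivisionError(f"zero denominator at row {row!r}")
    if (num <= 0).any() or (den < 0).any():
        raise ValueError("ratio requires positive raw trait values")
    log_ratio = np.log10(num / den)
    ag = table.column(against).astype(float)
    if not table.is_logged(against):
        if (ag <= 0).any():
            raise ValueError(f"column {against!r} must be positive to log")
        ag = np.log10(ag)
    name_r, name_a = f"log_ratio_{numerator}_{denominator}", f"log_{against}"
    data = pd.DataFrame({
        "species": table.species.values,
        name_r: log_ratio.values,
        name_a: ag.values,
    }, index=table.data.index)
    rtab = TraitTable(data, species_col=table.species_col,
                      log_cols=(name_r, name_a), log_base=10.0)
    return _fit(rtab, name_r, [name_a], engine, cov=cov,
                lambda_mode=lambda_mode)


def elevation_diff_correlation(pair_a: PairwiseShiftMatrix,
                               pair_b: PairwiseShiftMatrix):
    """Correlation of the two structures' pairwise elevation differences.

    Pearson correlation across the g(g-1)/2 upper-triangle values.
    Exploratory only: the pairs share species and are therefore not
    independent observations, and non-significant differences enter the
    correlation; the returned caveats string records this.
    """
    if list(pair_a.groups) != list(pair_b.groups):
        raise ValueError("shift matrices cover different group sets")
    da = pair_a.upper_triangle()
    db = pair_b.upper_triangle()
    if len(da) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    r, p = scipy.stats.pearsonr(da, db)
    caveats = ("exploratory: pairwise differences share species and are not "
               "independent; non-significant differences are included; "
               f"nominal p = {p:.3g} overstates evidence")
    return float(r), len(da), caveats


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

@dataclass
class TradeoffReport:
    """Bundle of every trade-off diagnostic run on one dataset."""
    dataset: str
    conditional: LinearFit | None = None
    residual: LinearFit | None = None
    sma_a: object = None                # MultiGroupSMAResults, structure A
    sma_b: object = None
    classification: ShiftClassification | None = None
    ratio_fit: LinearFit | None = None
    elevation_corr: tuple | None = None
    notes: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"Trade-off report: {self.dataset}", "=" * 40]
        if self.conditional is not None:
            focal = self.conditional.predictors[-1]
            lines += ["-- conditional association (partial coefficient on "
                      f"{focal}) --", self.conditional.summary(), ""]
        if self.residual is not None:
            lines += ["-- residual association --", self.residual.summary(),
                      ""]
        for tag, res in (("A", self.sma_a), ("B", self.sma_b)):
            if res is not None:
                lines += [f"-- grouped SMA, structure {tag} --",
                          res.summary(), ""]
        if self.classification is not None:
            lines += [self.classification.summary(), ""]
        if self.ratio_fit is not None:
            lines += ["-- ratio vs size --", self.ratio_fit.summary(), ""]
        if self.elevation_corr is not None:
            r, n, caveats = self.elevation_corr
            lines += [f"Elevation-difference correlation: r = {r:.3f} "
                      f"(n_pairs = {n}; {caveats})", ""]
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines)

    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(self.summary() + "\n")
        for name, fit in (("conditional", self.conditional),
                          ("residual", self.residual),
                          ("ratio_size", self.ratio_fit)):
            if fit is not None:
                fit.to_frame().to_csv(out / f"fit_{name}.csv", index=False)
                fit.resid.rename("residual").to_csv(
                    out / f"residuals_{name}.csv",
                    index_label="observation_id")
        if self.classification is not None:
            self.classification.pairs.to_csv(out / "classification.csv",
                                             index=False)
        for tag, res in (("A", self.sma_a), ("B", self.sma_b)):
            if res is not None:
                res.pairwise.to_long_frame().to_csv(
                    out / f"pairwise_{tag}.csv", index=False)
                res.pairwise.to_square_frame().to_csv(
                    out / f"pairwise_{tag}_matrix.csv")
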