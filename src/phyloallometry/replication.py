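"""Recipes for re-running the headline analyses on the original datasets.

These functions encode, end to end, the analyses whose statistics the
package is designed to reproduce on the published *Drosophila* sensory
datasets (59-species eye/funiculus surface areas; six-species brain
neuropil volumes; six-species eye-antennal imaginal disc areas). The data
themselves are not bundled — they live in the Open Access Data Repository
of the Max Planck Society (doi 10.17617/3.1D) — so each recipe takes file
paths and a column mapping and returns a :class:`~.tradeoff.TradeoffReport`.

Expected layouts (delimited text, header row):

* head sensory table — one row per species: species label, eye surface
  area (ESA), funiculus surface area (FSA), body length; plus a Newick
  tree covering the species.
* brain / disc tables — one row per individual: species label, the two
  focal structures (optic lobe and antennal lobe volumes, or eye- and
  antennal-disc portions) and the size control (rest-of-brain volume;
  total disc area, from which rest-of-disc = total - focal portions).

Note the published phylogenetic statistics came from an MCMC sampler, so
maximum-likelihood PGLS reproduces them approximately; the SMA and OLS
statistics are exact-algorithm quantities and should match to printed
precision.
"""

from __future__ import annotations

import numpy as np

from .pgls import anova_term, ols_fit
from .sma import MultiGroupSMA
from .tradeoff import (TradeoffReport, classify_shifts,
                       conditional_association, elevation_diff_correlation,
                       ratio_size_test, residual_association)
from .traits import align_taxa, read_trait_table
from .tree import read_newick


def replicate_head_sensory(tree_path, table_path, esa="ESA", fsa="FSA",
                           body="body_length", species_col="species",
                           lambda_mode="ml") -> TradeoffReport:
    """59-species eye/funiculus analysis: PGLS allometry, residual
    association, and the EF-ratio diagnostics."""
    tree = read_newick(tree_path)
    table = read_trait_table(table_path, species_col=species_col,
                             log_cols=[esa, fsa, body])
    tree, table, dropped = align_taxa(tree, table)
    cov = tree.bm_covariance()
    report = TradeoffReport(dataset="head_sensory")
    report.conditional = conditional_association(
        table, focal_y=esa, focal_x=fsa, control=body, engine="pgls",
        cov=cov, lambda_mode=lambda_mode)
    report.residual = residual_association(
        table, esa, fsa, control=body, engine="pgls", cov=cov,
        lambda_mode=lambda_mode)
    # EF ratio needs raw-scale areas: undo the on-read log transform
    base = table.log_base
    raw = table.with_column(f"raw_{esa}", base ** table.column(esa)) \
               .with_column(f"raw_{fsa}", base ** table.column(fsa))
    report.ratio_fit = ratio_size_test(
        raw, numerator=f"raw_{esa}", denominator=f"raw_{fsa}", against=esa,
        engine="pgls", cov=cov, lambda_mode=lambda_mode)
    ef = raw.column(f"raw_{esa}") / raw.column(f"raw_{fsa}")
    report.notes.append(f"EF ratio range: {ef.min():.2f} to {ef.max():.2f}")
    if dropped["tree"] or dropped["table"]:
        report.notes.append(f"taxa dropped during alignment: {dropped}")
    return report


def _individual_level(table_path, focal_a, focal_b, control, species_col,
                      dataset, total=None, min_shift=0.1,
                      alpha=0.05) -> TradeoffReport:
    log_cols = [focal_a, focal_b] + ([total] if total else [control])
    table = read_trait_table(table_path, species_col=species_col,
                             log_cols=[])
    if total is not None:
        # rest-of-disc style control: total minus both focal portions,
        # on the raw scale, before logging
        rod = table.column(total) - table.column(focal_a) \
            - table.column(focal_b)
        if (rod <= 0).any():
            raise ValueError("non-positive rest-of-structure value; check "
                             "the total column")
        table = table.with_column(control, rod)
    for col in (focal_a, focal_b, control):
        table = table.with_column(f"log_{col}",
                                  np.log10(table.column(col)), logged=True)
    la, lb, lc = f"log_{focal_a}", f"log_{focal_b}", f"log_{control}"
    report = TradeoffReport(dataset=dataset)
    report.conditional = conditional_association(
        table, focal_y=la, focal_x=lb, control=lc, engine="ols",
        species_fixed=True)
    report.residual = residual_association(table, la, lb, control=lc,
                                           engine="ols")
    report.sma_a = MultiGroupSMA.from_table(table, x=lc, y=la).fit()
    report.sma_b = MultiGroupSMA.from_table(table, x=lc, y=lb).fit()
    report.classification = classify_shifts(
        report.sma_a.pairwise, report.sma_b.pairwise, min_shift=min_shift,
        alpha=alpha)
    report.elevation_corr = elevation_diff_correlation(
        report.sma_a.pairwise, report.sma_b.pairwise)
    # species effect on top of the full allometric model
    full = ols_fit(table, la, [lc, lb], species_fixed=True)
    reduced = ols_fit(table, la, [lc, lb], species_fixed=False)
    report.notes.append(anova_term(full, reduced, term="species").summary())
    return report


def replicate_brain(table_path, ol="OL", al="AL", rob="RoB",
                    species_col="species", **kw) -> TradeoffReport:
    """Six-species optic-lobe / antennal-lobe analysis (volumes, one row
    per individual brain)."""
    return _individual_level(table_path, ol, al, rob, species_col,
                             dataset="brain_neuropil", **kw)


def replicate_disc(table_path, edp="EDp", adp="ADp", total="disc_total",
                   species_col="species", **kw) -> TradeoffReport:
    """Six-species imaginal-disc analysis; the size control is the disc
    area left after removing both focal portions (rest of disc)."""
    return _individual_level(table_path, edp, adp, "RoD", species_col,
                             dataset="imaginal_disc", total=total, **kw)
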