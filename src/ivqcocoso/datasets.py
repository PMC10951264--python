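"""Bundled example datasets and the synthetic matrix generator.

Two worked examples ship with the package:

* ``supplier`` — six supplier objects O1..O6 rated on five attributes
  a1..a5 by two information sources.  No rung is stated for this example;
  fixtures default to q = 3, the first rung at which every cell of both the
  raw tables and the inclusive envelope is valid (one envelope cell,
  O2/a3 = <[0.1, 0.6], [0.2, 0.9]>, violates the q = 2 constraint).
* ``sepsis`` — six suspected-sepsis patients A1..A6 assessed by two experts
  P1, P2 on nine clinical attributes C1..C9 (temperature, pulse, pain level,
  SaO2, blood pressure, level of consciousness, capillary refill time, urine
  output, ScvO2/base-deficiency degree); q = 2, the rung uniquely consistent
  with the published intermediate tables.  C1, C4, C6, C7, C8 are benefit
  criteria; C2, C3, C5, C9 are cost criteria.

Expected intermediate/outcome tables of both worked chains are embedded so
every pipeline stage has a cell-level golden fixture.  Known misprints in
the published tables are corrected here and documented in
``docs/methods.md``:

* row O6 of the expected compromised supplier aggregate repeats the second
  source's row verbatim in print; the fixture stores the componentwise mean
  that the aggregation rule defines;
* two sepsis source cells (X2 cell C3/A2 lower membership bound, X1 cell
  C8/A6 upper non-membership bound) are transcribed as 0.2 and 0.6 — the
  unique single-digit values that make the published aggregate, envelope and
  standardized tables mutually consistent with the aggregation and entropy
  definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import FuzzyDecisionMatrix, WeightVector

__all__ = [
    "SyntheticSpec",
    "generate_synthetic",
    "supplier_sources",
    "supplier_expected",
    "sepsis_sources",
    "sepsis_directions",
    "sepsis_expected",
    "sepsis_expected_standardized",
    "sepsis_published_weights",
    "sepsis_expected_aggregates",
    "sepsis_expected_compromise_scores",
    "SEPSIS_RANKING_COMPROMISED",
    "SEPSIS_RANKING_INCLUSIVE",
    "FIXTURES",
]

# --------------------------------------------------------------------------
# Supplier example (two sources, 6 alternatives x 5 attributes, q = 3)
# --------------------------------------------------------------------------

SUPPLIER_ALTS = ("O1", "O2", "O3", "O4", "O5", "O6")
SUPPLIER_CRITS = ("a1", "a2", "a3", "a4", "a5")

# cell = (mu_lo, mu_hi, nu_lo, nu_hi); rows are alternatives
_SUPPLIER_S1 = [
    [(0.1, 0.3, 0.4, 0.5), (0.4, 0.6, 0.2, 0.5), (0.2, 0.4, 0.4, 0.6), (0.2, 0.4, 0.2, 0.6), (0.1, 0.3, 0.1, 0.3)],
    [(0.5, 0.8, 0.1, 0.3), (0.3, 0.5, 0.3, 0.8), (0.4, 0.6, 0.2, 0.4), (0.4, 0.6, 0.2, 0.5), (0.1, 0.3, 0.1, 0.3)],
    [(0.8, 0.9, 0.3, 0.4), (0.4, 0.6, 0.2, 0.6), (0.1, 0.2, 0.6, 0.8), (0.3, 0.5, 0.1, 0.2), (0.1, 0.3, 0.1, 0.3)],
    [(0.5, 0.6, 0.2, 0.4), (0.4, 0.6, 0.4, 0.5), (0.2, 0.6, 0.4, 0.8), (0.4, 0.6, 0.2, 0.5), (0.3, 0.4, 0.5, 0.7)],
    [(0.6, 0.7, 0.3, 0.5), (0.1, 0.3, 0.3, 0.6), (0.4, 0.8, 0.1, 0.4), (0.1, 0.3, 0.1, 0.3), (0.3, 0.6, 0.2, 0.7)],
    [(0.4, 0.7, 0.3, 0.5), (0.4, 0.7, 0.2, 0.4), (0.2, 0.4, 0.5, 0.8), (0.1, 0.3, 0.1, 0.3), (0.3, 0.8, 0.2, 0.5)],
]

_SUPPLIER_S2 = [
    [(0.2, 0.4, 0.2, 0.6), (0.4, 0.7, 0.2, 0.3), (0.3, 0.5, 0.2, 0.3), (0.3, 0.4, 0.3, 0.5), (0.2, 0.4, 0.2, 0.3)],
    [(0.3, 0.5, 0.2, 0.3), (0.4, 0.5, 0.2, 0.6), (0.1, 0.2, 0.8, 0.9), (0.1, 0.2, 0.3, 0.4), (0.5, 0.7, 0.1, 0.3)],
    [(0.5, 0.6, 0.2, 0.3), (0.2, 0.4, 0.5, 0.6), (0.3, 0.7, 0.2, 0.8), (0.6, 0.7, 0.1, 0.3), (0.3, 0.6, 0.1, 0.3)],
    [(0.3, 0.5, 0.1, 0.2), (0.2, 0.6, 0.3, 0.4), (0.1, 0.2, 0.3, 0.5), (0.2, 0.3, 0.1, 0.6), (0.4, 0.6, 0.2, 0.3)],
    [(0.2, 0.8, 0.1, 0.2), (0.5, 0.7, 0.2, 0.6), (0.2, 0.6, 0.3, 0.6), (0.2, 0.4, 0.1, 0.4), (0.1, 0.2, 0.7, 0.8)],
    [(0.1, 0.3, 0.3, 0.5), (0.6, 0.8, 0.2, 0.4), (0.4, 0.6, 0.2, 0.3), (0.2, 0.6, 0.2, 0.4), (0.2, 0.3, 0.1, 0.3)],
]

# Expected compromised aggregate.  Rows O1..O5 are the printed table; row O6
# is the componentwise mean (the printed row repeats source S2 by mistake).
_SUPPLIER_COMPROMISED = [
    [(0.15, 0.35, 0.3, 0.55), (0.4, 0.65, 0.2, 0.4), (0.25, 0.45, 0.3, 0.45), (0.25, 0.4, 0.25, 0.55), (0.15, 0.35, 0.15, 0.3)],
    [(0.4, 0.65, 0.15, 0.3), (0.35, 0.5, 0.25, 0.7), (0.25, 0.4, 0.5, 0.65), (0.25, 0.4, 0.25, 0.45), (0.3, 0.5, 0.1, 0.3)],
    [(0.65, 0.75, 0.25, 0.35), (0.3, 0.5, 0.35, 0.6), (0.2, 0.45, 0.4, 0.8), (0.45, 0.6, 0.1, 0.25), (0.2, 0.45, 0.1, 0.3)],
    [(0.4, 0.55, 0.15, 0.3), (0.3, 0.6, 0.35, 0.45), (0.15, 0.4, 0.35, 0.65), (0.3, 0.45, 0.15, 0.55), (0.35, 0.5, 0.35, 0.5)],
    [(0.4, 0.75, 0.2, 0.35), (0.3, 0.5, 0.25, 0.6), (0.3, 0.7, 0.2, 0.5), (0.15, 0.35, 0.1, 0.35), (0.2, 0.4, 0.45, 0.75)],
    [(0.25, 0.5, 0.3, 0.5), (0.5, 0.75, 0.2, 0.4), (0.3, 0.5, 0.35, 0.55), (0.15, 0.45, 0.15, 0.35), (0.25, 0.55, 0.15, 0.4)],
]

_SUPPLIER_INCLUSIVE = [
    [(0.1, 0.4, 0.2, 0.6), (0.4, 0.7, 0.2, 0.5), (0.2, 0.5, 0.2, 0.6), (0.2, 0.4, 0.2, 0.6), (0.1, 0.4, 0.1, 0.3)],
    [(0.3, 0.8, 0.1, 0.3), (0.3, 0.5, 0.2, 0.8), (0.1, 0.6, 0.2, 0.9), (0.1, 0.6, 0.2, 0.5), (0.1, 0.7, 0.1, 0.3)],
    [(0.5, 0.9, 0.2, 0.4), (0.2, 0.6, 0.2, 0.6), (0.1, 0.7, 0.2, 0.8), (0.3, 0.7, 0.1, 0.3), (0.1, 0.6, 0.1, 0.3)],
    [(0.3, 0.6, 0.1, 0.4), (0.2, 0.6, 0.3, 0.5), (0.1, 0.6, 0.3, 0.8), (0.2, 0.6, 0.1, 0.6), (0.3, 0.6, 0.2, 0.7)],
    [(0.2, 0.8, 0.1, 0.5), (0.1, 0.7, 0.2, 0.6), (0.2, 0.8, 0.1, 0.6), (0.1, 0.4, 0.1, 0.4), (0.1, 0.6, 0.2, 0.8)],
    [(0.1, 0.7, 0.3, 0.5), (0.4, 0.8, 0.2, 0.4), (0.2, 0.6, 0.2, 0.8), (0.1, 0.6, 0.1, 0.4), (0.2, 0.8, 0.1, 0.5)],
]

# --------------------------------------------------------------------------
# Sepsis example (two experts, 6 patients x 9 attributes, q = 2)
# --------------------------------------------------------------------------

SEPSIS_ALTS = ("A1", "A2", "A3", "A4", "A5", "A6")
SEPSIS_CRITS = ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9")

SEPSIS_DIRECTIONS = {
    "C1": "benefit", "C2": "cost", "C3": "cost", "C4": "benefit", "C5": "cost",
    "C6": "benefit", "C7": "benefit", "C8": "benefit", "C9": "cost",
}

# Transcribed criterion-major (one row per criterion C1..C9, columns A1..A6).
_SEPSIS_X1 = [
    [(0.2, 0.4, 0.5, 0.6), (0.1, 0.2, 0.6, 0.7), (0.1, 0.2, 0.6, 0.8), (0.4, 0.6, 0.2, 0.4), (0.2, 0.6, 0.7, 0.8), (0.1, 0.4, 0.7, 0.8)],
    [(0.2, 0.3, 0.4, 0.5), (0.1, 0.3, 0.2, 0.6), (0.1, 0.2, 0.1, 0.7), (0.1, 0.2, 0.4, 0.5), (0.4, 0.8, 0.1, 0.2), (0.1, 0.4, 0.7, 0.8)],
    [(0.3, 0.4, 0.5, 0.8), (0.2, 0.5, 0.5, 0.6), (0.3, 0.6, 0.6, 0.7), (0.2, 0.3, 0.5, 0.6), (0.1, 0.5, 0.4, 0.7), (0.3, 0.4, 0.65, 0.7)],
    [(0.5, 0.7, 0.1, 0.2), (0.4, 0.7, 0.1, 0.3), (0.5, 0.7, 0.1, 0.4), (0.2, 0.3, 0.1, 0.2), (0.4, 0.6, 0.5, 0.8), (0.2, 0.3, 0.6, 0.9)],
    [(0.3, 0.4, 0.4, 0.6), (0.1, 0.4, 0.4, 0.6), (0.1, 0.2, 0.3, 0.7), (0.4, 0.6, 0.2, 0.3), (0.3, 0.4, 0.3, 0.4), (0.2, 0.6, 0.5, 0.6)],
    [(0.1, 0.4, 0.3, 0.6), (0.2, 0.4, 0.3, 0.6), (0.5, 0.6, 0.1, 0.3), (0.2, 0.3, 0.1, 0.2), (0.1, 0.4, 0.5, 0.7), (0.2, 0.3, 0.4, 0.6)],
    [(0.2, 0.8, 0.1, 0.2), (0.3, 0.7, 0.2, 0.3), (0.6, 0.8, 0.1, 0.3), (0.7, 0.8, 0.3, 0.4), (0.3, 0.4, 0.5, 0.8), (0.1, 0.2, 0.35, 0.4)],
    [(0.4, 0.7, 0.1, 0.3), (0.2, 0.6, 0.2, 0.4), (0.1, 0.8, 0.2, 0.3), (0.5, 0.7, 0.3, 0.5), (0.3, 0.4, 0.5, 0.6), (0.1, 0.2, 0.4, 0.6)],
    [(0.2, 0.7, 0.2, 0.3), (0.4, 0.7, 0.1, 0.3), (0.6, 0.8, 0.2, 0.3), (0.1, 0.3, 0.5, 0.6), (0.5, 0.6, 0.7, 0.8), (0.4, 0.5, 0.55, 0.6)],
]

_SEPSIS_X2 = [
    [(0.3, 0.4, 0.5, 0.6), (0.1, 0.3, 0.5, 0.7), (0.2, 0.3, 0.3, 0.4), (0.3, 0.5, 0.4, 0.5), (0.4, 0.6, 0.7, 0.8), (0.3, 0.4, 0.5, 0.6)],
    [(0.1, 0.3, 0.4, 0.5), (0.1, 0.2, 0.4, 0.6), (0.1, 0.3, 0.1, 0.5), (0.3, 0.4, 0.2, 0.3), (0.6, 0.7, 0.3, 0.4), (0.1, 0.3, 0.5, 0.7)],
    [(0.4, 0.5, 0.5, 0.8), (0.2, 0.5, 0.4, 0.5), (0.5, 0.6, 0.6, 0.7), (0.1, 0.2, 0.4, 0.6), (0.3, 0.7, 0.4, 0.5), (0.5, 0.6, 0.65, 0.7)],
    [(0.6, 0.7, 0.1, 0.2), (0.6, 0.7, 0.1, 0.4), (0.3, 0.4, 0.2, 0.4), (0.2, 0.4, 0.4, 0.6), (0.2, 0.6, 0.5, 0.7), (0.4, 0.5, 0.5, 0.7)],
    [(0.2, 0.4, 0.5, 0.6), (0.2, 0.4, 0.2, 0.6), (0.2, 0.3, 0.3, 0.7), (0.4, 0.6, 0.2, 0.3), (0.7, 0.8, 0.3, 0.4), (0.4, 0.6, 0.3, 0.4)],
    [(0.2, 0.3, 0.1, 0.6), (0.3, 0.4, 0.2, 0.6), (0.3, 0.6, 0.1, 0.3), (0.1, 0.3, 0.6, 0.7), (0.1, 0.2, 0.7, 0.9), (0.3, 0.5, 0.6, 0.7)],
    [(0.1, 0.8, 0.2, 0.4), (0.5, 0.7, 0.4, 0.5), (0.6, 0.8, 0.1, 0.3), (0.5, 0.6, 0.3, 0.4), (0.2, 0.7, 0.3, 0.7), (0.1, 0.2, 0.35, 0.4)],
    [(0.4, 0.6, 0.2, 0.3), (0.5, 0.6, 0.1, 0.4), (0.2, 0.5, 0.2, 0.3), (0.5, 0.6, 0.1, 0.2), (0.1, 0.3, 0.6, 0.7), (0.5, 0.6, 0.5, 0.6)],
    [(0.3, 0.7, 0.1, 0.3), (0.4, 0.5, 0.1, 0.2), (0.6, 0.8, 0.2, 0.3), (0.1, 0.2, 0.7, 0.8), (0.4, 0.5, 0.6, 0.7), (0.6, 0.7, 0.55, 0.6)],
]

_SEPSIS_COMPROMISED = [
    [(0.25, 0.4, 0.5, 0.6), (0.1, 0.25, 0.55, 0.7), (0.15, 0.25, 0.45, 0.6), (0.35, 0.55, 0.3, 0.45), (0.3, 0.6, 0.7, 0.8), (0.2, 0.4, 0.6, 0.7)],
    [(0.15, 0.3, 0.4, 0.5), (0.1, 0.25, 0.3, 0.6), (0.1, 0.25, 0.1, 0.6), (0.2, 0.3, 0.3, 0.4), (0.5, 0.75, 0.2, 0.3), (0.1, 0.35, 0.6, 0.75)],
    [(0.35, 0.45, 0.5, 0.8), (0.2, 0.5, 0.45, 0.55), (0.4, 0.6, 0.6, 0.7), (0.15, 0.25, 0.45, 0.6), (0.2, 0.6, 0.4, 0.6), (0.4, 0.5, 0.65, 0.7)],
    [(0.55, 0.7, 0.1, 0.2), (0.5, 0.7, 0.1, 0.35), (0.4, 0.55, 0.15, 0.4), (0.2, 0.35, 0.25, 0.4), (0.3, 0.6, 0.5, 0.75), (0.3, 0.4, 0.55, 0.8)],
    [(0.25, 0.4, 0.45, 0.6), (0.15, 0.4, 0.3, 0.6), (0.15, 0.25, 0.3, 0.7), (0.4, 0.6, 0.2, 0.3), (0.5, 0.6, 0.3, 0.4), (0.3, 0.6, 0.4, 0.5)],
    [(0.15, 0.35, 0.2, 0.6), (0.25, 0.4, 0.25, 0.6), (0.4, 0.6, 0.1, 0.3), (0.15, 0.3, 0.35, 0.45), (0.1, 0.3, 0.6, 0.8), (0.25, 0.4, 0.5, 0.65)],
    [(0.15, 0.8, 0.15, 0.3), (0.4, 0.7, 0.3, 0.4), (0.6, 0.8, 0.1, 0.3), (0.6, 0.7, 0.3, 0.4), (0.25, 0.55, 0.4, 0.75), (0.1, 0.2, 0.35, 0.4)],
    [(0.4, 0.65, 0.15, 0.3), (0.35, 0.6, 0.15, 0.4), (0.15, 0.65, 0.2, 0.3), (0.5, 0.65, 0.2, 0.35), (0.2, 0.35, 0.55, 0.65), (0.3, 0.4, 0.45, 0.6)],
    [(0.25, 0.7, 0.15, 0.3), (0.4, 0.6, 0.1, 0.25), (0.6, 0.8, 0.2, 0.3), (0.1, 0.25, 0.6, 0.7), (0.45, 0.55, 0.65, 0.75), (0.5, 0.6, 0.55, 0.6)],
]

_SEPSIS_INCLUSIVE = [
    [(0.2, 0.4, 0.5, 0.6), (0.1, 0.3, 0.5, 0.7), (0.1, 0.3, 0.3, 0.8), (0.3, 0.6, 0.2, 0.5), (0.2, 0.6, 0.7, 0.8), (0.1, 0.4, 0.5, 0.8)],
    [(0.1, 0.3, 0.4, 0.5), (0.1, 0.3, 0.2, 0.6), (0.1, 0.3, 0.1, 0.7), (0.1, 0.4, 0.2, 0.5), (0.4, 0.8, 0.1, 0.4), (0.1, 0.4, 0.5, 0.8)],
    [(0.3, 0.5, 0.5, 0.8), (0.2, 0.5, 0.4, 0.6), (0.3, 0.6, 0.6, 0.7), (0.1, 0.3, 0.4, 0.6), (0.1, 0.7, 0.4, 0.7), (0.3, 0.6, 0.65, 0.7)],
    [(0.5, 0.7, 0.1, 0.2), (0.4, 0.7, 0.1, 0.4), (0.3, 0.7, 0.1, 0.4), (0.2, 0.4, 0.1, 0.6), (0.2, 0.6, 0.5, 0.8), (0.2, 0.5, 0.5, 0.8)],
    [(0.2, 0.4, 0.4, 0.6), (0.1, 0.4, 0.2, 0.6), (0.1, 0.3, 0.3, 0.7), (0.4, 0.6, 0.2, 0.3), (0.3, 0.8, 0.3, 0.4), (0.2, 0.6, 0.3, 0.6)],
    [(0.1, 0.4, 0.1, 0.6), (0.2, 0.4, 0.2, 0.6), (0.3, 0.6, 0.1, 0.3), (0.1, 0.3, 0.1, 0.7), (0.1, 0.4, 0.5, 0.9), (0.2, 0.5, 0.4, 0.7)],
    [(0.1, 0.8, 0.1, 0.4), (0.3, 0.7, 0.2, 0.5), (0.6, 0.8, 0.1, 0.3), (0.5, 0.8, 0.3, 0.4), (0.2, 0.7, 0.3, 0.7), (0.1, 0.2, 0.35, 0.4)],
    [(0.4, 0.7, 0.1, 0.3), (0.2, 0.6, 0.1, 0.4), (0.1, 0.8, 0.2, 0.3), (0.5, 0.7, 0.1, 0.5), (0.1, 0.4, 0.5, 0.7), (0.1, 0.6, 0.4, 0.6)],
    [(0.2, 0.7, 0.1, 0.3), (0.4, 0.7, 0.1, 0.3), (0.6, 0.8, 0.2, 0.3), (0.1, 0.3, 0.5, 0.8), (0.4, 0.6, 0.6, 0.8), (0.4, 0.7, 0.55, 0.6)],
]

# Standardized (entropy q=2, k=1/3) and column-normalized decision matrix;
# criterion-major, columns A1..A6.  Each row sums to 1 over the alternatives.
_SEPSIS_STANDARDIZED = [
    [0.182420, 0.153717, 0.159079, 0.174640, 0.159815, 0.170329],
    [0.155580, 0.165814, 0.181164, 0.182923, 0.162936, 0.151583],
    [0.214251, 0.157638, 0.112250, 0.216447, 0.152269, 0.147145],
    [0.160550, 0.164578, 0.176102, 0.141195, 0.190311, 0.167263],
    [0.145770, 0.182718, 0.237836, 0.178478, 0.127599, 0.127599],
    [0.160046, 0.173863, 0.170409, 0.152562, 0.151986, 0.191134],
    [0.120456, 0.182259, 0.159961, 0.203587, 0.188439, 0.145298],
    [0.154684, 0.167102, 0.138998, 0.172985, 0.179847, 0.186383],
    [0.241146, 0.195087, 0.213716, 0.190993, 0.117912, 0.041146],
]

# Published objective attribute weights (sum 1.00184178, kept verbatim: this
# exact vector reproduces the downstream score tables).
_SEPSIS_WEIGHTS = {
    "C1": 0.11373375, "C2": 0.10907751, "C3": 0.10671905, "C4": 0.11856914,
    "C5": 0.10717358, "C6": 0.11235538, "C7": 0.11573375, "C8": 0.11367079,
    "C9": 0.10480883,
}

_SEPSIS_AGGREGATES = {
    "S": [0.17002150, 0.17155811, 0.17206130, 0.17916780, 0.16012616, 0.14890692],
    "M": [7.37434996, 7.39336800, 7.38270240, 7.42561249, 7.32930866, 7.22983220],
}

_SEPSIS_SCORES = {
    "s1": [0.167143782, 0.167599165, 0.167374019, 0.168482125, 0.165926673, 0.163474236],
    "s2": [2.161786281, 2.174736032, 2.176640035, 2.230299637, 2.089103153, 2.0],
    "s3": [0.992056466, 0.994759325, 0.993423006, 1.0, 0.984832504, 0.970276436],
}

SEPSIS_RANKING_COMPROMISED = ("A4", "A2", "A3", "A1", "A5", "A6")
SEPSIS_RANKING_INCLUSIVE = ("A2", "A1", "A3", "A5", "A4", "A6")


def _from_alt_major(rows, alts, crits, q, source_id):
    values = np.array([[cell for cell in row] for row in rows], dtype=float)
    return FuzzyDecisionMatrix(alts, crits, values, q=q, source_id=source_id)


def _from_crit_major(rows, alts, crits, q, source_id):
    values = np.array(rows, dtype=float).transpose(1, 0, 2)
    return FuzzyDecisionMatrix(alts, crits, values, q=q, source_id=source_id)


def supplier_sources(q: int = 3) -> list[FuzzyDecisionMatrix]:
    """The two supplier-example source matrices (default rung q=3)."""
    return [
        _from_alt_major(_SUPPLIER_S1, SUPPLIER_ALTS, SUPPLIER_CRITS, q, "S1"),
        _from_alt_major(_SUPPLIER_S2, SUPPLIER_ALTS, SUPPLIER_CRITS, q, "S2"),
    ]


def supplier_expected(strategy: str = "compromised", q: int = 3) -> FuzzyDecisionMatrix:
    """Expected supplier aggregate for the given strategy."""
    rows = {"compromised": _SUPPLIER_COMPROMISED, "inclusive": _SUPPLIER_INCLUSIVE}[strategy]
    return _from_alt_major(rows, SUPPLIER_ALTS, SUPPLIER_CRITS, q, f"expected-{strategy}")


def sepsis_sources() -> list[FuzzyDecisionMatrix]:
    """The two sepsis expert matrices X1 (P1) and X2 (P2) at q=2."""
    return [
        _from_crit_major(_SEPSIS_X1, SEPSIS_ALTS, SEPSIS_CRITS, 2, "P1"),
        _from_crit_major(_SEPSIS_X2, SEPSIS_ALTS, SEPSIS_CRITS, 2, "P2"),
    ]


def sepsis_directions() -> dict[str, str]:
    return dict(SEPSIS_DIRECTIONS)


def sepsis_expected(strategy: str = "compromised") -> FuzzyDecisionMatrix:
    """Expected sepsis aggregate (X3 compromised / X4 inclusive)."""
    rows = {"compromised": _SEPSIS_COMPROMISED, "inclusive": _SEPSIS_INCLUSIVE}[strategy]
    return _from_crit_major(rows, SEPSIS_ALTS, SEPSIS_CRITS, 2, f"expected-{strategy}")


def sepsis_expected_standardized() -> pd.DataFrame:
    """Expected standardized matrix (alternatives x criteria, columns sum to 1)."""
    return pd.DataFrame(
        np.array(_SEPSIS_STANDARDIZED).T, index=list(SEPSIS_ALTS), columns=list(SEPSIS_CRITS)
    )


def sepsis_published_weights() -> WeightVector:
    """Published attribute weights, unnormalized (sum 1.00184178)."""
    return WeightVector(pd.Series(_SEPSIS_WEIGHTS), normalized=False)


def sepsis_expected_aggregates() -> pd.DataFrame:
    """Expected weighted sums S and power sums M per alternative."""
    return pd.DataFrame(_SEPSIS_AGGREGATES, index=list(SEPSIS_ALTS))


def sepsis_expected_compromise_scores() -> pd.DataFrame:
    """Expected compromise-score triples (epsilon = 0.5)."""
    return pd.DataFrame(_SEPSIS_SCORES, index=list(SEPSIS_ALTS))


#: Registry used by the CLI `fixtures` subcommand.
FIXTURES = {
    "supplier-sources": lambda: supplier_sources(),
    "supplier-compromised": lambda: [supplier_expected("compromised")],
    "supplier-inclusive": lambda: [supplier_expected("inclusive")],
    "sepsis-sources": lambda: sepsis_sources(),
    "sepsis-compromised": lambda: [sepsis_expected("compromised")],
    "sepsis-inclusive": lambda: [sepsis_expected("inclusive")],
}


# --------------------------------------------------------------------------
# Synthetic generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Shape, rung and seed for a synthetic multi-expert dataset.

    Defaults mirror the sepsis study: six alternatives, nine criteria, two
    experts, rung 2, and four of nine criteria treated as costs.
    """

    n_alternatives: int = 6
    n_criteria: int = 9
    n_sources: int = 2
    q: int = 2
    cost_fraction: float = 4.0 / 9.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_alternatives, self.n_criteria, self.n_sources) < 1:
            raise ValueError("dimensions must be positive")
        if not 0.0 <= self.cost_fraction <= 1.0:
            raise ValueError("cost_fraction must lie in [0, 1]")


def generate_synthetic(spec: SyntheticSpec) -> tuple[list[FuzzyDecisionMatrix], dict[str, str]]:
    """Draw valid-by-construction multi-expert matrices plus directions.

    Sampling per cell: ``mu_hi ~ U(0, 1)``, ``nu_hi ~ U(0, (1-mu_hi^q)^(1/q))``
    (so the rung constraint holds by construction), then ``mu_lo ~ U(0, mu_hi)``
    and ``nu_lo ~ U(0, nu_hi)``.  Deterministic for a fixed seed.  The first
    ``round(cost_fraction * n_criteria)`` criteria are marked as costs.
    """
    rng = np.random.default_rng(spec.seed)
    alts = tuple(f"A{i+1}" for i in range(spec.n_alternatives))
    crits = tuple(f"C{j+1}" for j in range(spec.n_criteria))
    shape = (spec.n_alternatives, spec.n_criteria)
    sources = []
    for s in range(spec.n_sources):
        mu_hi = rng.uniform(0.0, 1.0, shape)
        nu_hi = rng.uniform(0.0, (1.0 - mu_hi**spec.q) ** (1.0 / spec.q))
        mu_lo = rng.uniform(0.0, mu_hi)
        nu_lo = rng.uniform(0.0, nu_hi)
        values = np.stack([mu_lo, mu_hi, nu_lo, nu_hi], axis=-1)
        sources.append(
            FuzzyDecisionMatrix(alts, crits, values, q=spec.q, source_id=f"P{s+1}")
        )
    n_cost = round(spec.cost_fraction * spec.n_criteria)
    directions = {c: ("cost" if j < n_cost else "benefit") for j, c in enumerate(crits)}
    return sources, directions
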