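"""Published reference tables from the MCF-7 miR-155 overexpression screen.

Two small tables transcribed from the published screen of miR-155
target derepression in MCF-7 breast-cancer cells:

* ``eight_mer_cohort`` -- the sixteen increased-expression genes with a
  miR-155 8-mer seed site that survived the low-read filter, with the
  per-gene 3'UTR-shortening call (Yes/No) and the relative expression
  (miR-155 / vector RPKM fold).
* ``mapk_site_table`` -- six MAPK-pathway genes with their 7mer / 8mer
  seed-site counts and shortening call.

Known internal inconsistencies of the source, carried verbatim rather
than resolved: MAP3K14 is shortening "Yes" in the cohort table but "No"
in the MAPK table, and the cohort table holds eleven "Yes" rows while
the accompanying narrative mentions ten shortened transcripts.  The
screen narrative also fixes the cohort arithmetic this module's
paper-mimic preset reproduces: thirty increased 8-mer targets, fourteen
excluded for raw reads below ten in both lines, sixteen remaining.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "eight_mer_cohort",
    "mapk_site_table",
    "INCREASED_8MER_TOTAL",
    "LOW_READ_EXCLUDED",
    "RETAINED_COHORT",
]

#: Screen narrative counts: increased 8-mer targets, of which low-read.
INCREASED_8MER_TOTAL = 30
LOW_READ_EXCLUDED = 14
RETAINED_COHORT = INCREASED_8MER_TOTAL - LOW_READ_EXCLUDED  # 16

_COHORT_ROWS = [
    ("SPIN2B", True, 1.516575),
    ("GLT25D1", False, 1.557417),
    ("MAP3K14", True, 1.849516),
    ("CARS2", True, 1.862035),
    ("ARVCF", True, 2.292287),
    ("AGTRAP", True, 2.816578),
    ("MYLK", False, 3.222538),
    ("CARD10", True, 3.237354),
    ("IRF2BP2", True, 3.330693),
    ("CSNK1G2", False, 3.472894),
    ("TRMT61A", True, 3.627442),
    ("MAP3K10", True, 3.813621),
    ("CEBPB", True, 4.871474),
    ("PRKAR1B", True, 7.552545),
    ("SOCS1", False, 8.080313),
    ("SPOCK1", False, 20.33727),
]

_MAPK_ROWS = [
    ("RSK2", 1, 0, False),
    ("Rac1", 1, 0, True),
    ("k-Ras", 3, 0, False),
    ("KSR1", 0, 1, False),
    ("MAP3K14", 0, 1, False),
    ("MAP3K10", 0, 1, True),
]


def eight_mer_cohort() -> pd.DataFrame:
    """The sixteen retained increased-expression 8-mer targets.

    Columns: ``gene``, ``utr_shortening`` (bool), ``relative_expression``
    (miR-155 / vector fold), ordered by ascending relative expression as
    published.
    """
    return pd.DataFrame(
        _COHORT_ROWS, columns=["gene", "utr_shortening", "relative_expression"]
    )


def mapk_site_table() -> pd.DataFrame:
    """MAPK-pathway genes with seed-site counts and shortening calls.

    Columns: ``gene``, ``n_7mer``, ``n_8mer``, ``utr_shortening``.
    """
    return pd.DataFrame(
        _MAPK_ROWS, columns=["gene", "n_7mer", "n_8mer", "utr_shortening"]
    )
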