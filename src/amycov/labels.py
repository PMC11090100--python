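"""Canonical label sets for amygdala subregion analyses.

Nine nuclei per hemisphere from FreeSurfer-style subfield segmentation,
plus the two whole-amygdala volumes. Column order is fixed package-wide:
tables, fingerprint grids and correlation matrices all follow it.
"""

from __future__ import annotations

#: The nine amygdala nuclei, per hemisphere.
NUCLEI = ("La", "Ba", "AB", "AAA", "Ce", "Me", "Co", "CAT", "PL")

NUCLEUS_NAMES = {
    "La": "lateral nucleus",
    "Ba": "basal nucleus",
    "AB": "accessory-basal nucleus",
    "AAA": "anterior-amygdaloid-area",
    "Ce": "central nucleus",
    "Me": "medial nucleus",
    "Co": "cortical nucleus",
    "CAT": "corticoamygdaloid-transition",
    "PL": "paralaminar nucleus",
}

#: 18 subregion seed columns, left hemisphere first.
SEED_COLUMNS = tuple(f"{h}_{n}" for h in ("L", "R") for n in NUCLEI)

#: Whole-amygdala volume columns.
WHOLE_AMYGDALA_COLUMNS = ("L_Amyg", "R_Amyg")

#: All 20 volume columns of a seed-volume table, in canonical order.
VOLUME_COLUMNS = SEED_COLUMNS + WHOLE_AMYGDALA_COLUMNS

#: Default covariates of the interaction model.
DEFAULT_COVARIATES = ("age", "sex", "tiv")
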