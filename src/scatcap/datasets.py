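"""Published reference values from the Cumberland Island bobcat scat survey.

The 2011-2012 noninvasive survey of the reintroduced bobcat population
on Cumberland Island, Georgia, published pairwise relatedness estimates
for the nine genotyped individuals (dyadic maximum likelihood and the
triadic likelihood estimator) together with the headline survey counts.
These printed values serve as desk-scale worked examples for the
summary operations in this package; the underlying genotypes and
spatial data live in the study's public data deposit and are not
redistributed here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: headline counts of the Cumberland Island survey
CUIS_COUNTS = {
    "scats_collected": 117,
    "bobcat_scats": 45,
    "coyote_scats": 46,
    "scats_retained": 21,  # consensus genotypes at >= 6 loci
    "individuals": 9,
}

#: mean weighted heterozygote-excess D reported for the nine individuals
CUIS_MEAN_WEIGHTED_D = 0.11


def load_cuis_relatedness() -> pd.DataFrame:
    """Published pairwise relatedness for the nine Cumberland Island bobcats.

    One row per unordered pair: ``r_ml`` (dyadic maximum likelihood),
    ``r_triadic`` (triadic likelihood) and the most-likely relationship
    category (U / FS / PO).
    """
    with resources.files("scatcap.data").joinpath("cuis_bobcat_relatedness.csv").open() as fh:
        return pd.read_csv(fh)
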