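"""Packaged fixtures: published count/MLE tables for the Hawaiian Montipora
RADseq analyses, so the D-statistic and delimitation-ranking stages run
offline without the original sequencing data.

``montipora_abba_baba_counts.tsv`` holds the 30 four-taxon hypotheses over
the five M. dilatata-complex samples (outgroup M. incrassata L27incra) with
their published ABBA/BABA counts and, for cross-checking, the published D,
p-value and direction columns.

``montipora_delim_models_synthetic_roster.yaml`` holds the six species-
delimitation partition models with their published log marginal-likelihood
estimates.  The per-sample roster in that file is a synthetic reconstruction
of the stated study design (see the file header); the groupings and MLEs are
the published ones.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

_COUNTS = "montipora_abba_baba_counts.tsv"
_MODELS = "montipora_delim_models_synthetic_roster.yaml"


def load_abba_baba_counts() -> pd.DataFrame:
    """The 30 published hypothesis/count rows (plus printed D/p/direction)."""
    with resources.files(__package__).joinpath(_COUNTS).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"id": str})


def load_delim_model_config() -> dict:
    """Raw YAML structure of the six delimitation models."""
    with resources.files(__package__).joinpath(_MODELS).open() as fh:
        return yaml.safe_load(fh)
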