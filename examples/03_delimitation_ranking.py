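"""Rank the six Montipora species-delimitation models by Bayes factor.

Each model is a sample -> species partition with a log marginal-likelihood
estimate (MLE) from path sampling.  BF = 2 x (MLE_reference - MLE_alt)
against model A (current taxonomy); negative values favour the alternative.
|BF| > 10 is decisive evidence.
"""

from reefadmix import load_partition_fixtures, rank_models
from reefadmix.delimitation import comparisons_to_frame

models = load_partition_fixtures()
frame = comparisons_to_frame(models, rank_models(models, reference_id="A"))
print(frame.to_string(index=False))
best = frame.iloc[0]
print(f"\nBest model: {best['model']} ({best['description']}), "
      f"MLE {best['mle']}, BF vs current taxonomy {best['bf']:.1f} (decisive).")
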