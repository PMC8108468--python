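"""Fit the opsin-count-versus-habitat-depth linear model.

Generates a 43-species depth table with a weak negative true slope
(population R-squared near 0.17), fits ordinary least squares and
prints the fit plus the shallow/deep contingency of multi-opsin species.
"""

from opsinminer import depth
from opsinminer import fixtures as fx

table = fx.make_depth_table(seed=1)
fit = depth.fit_depth_model(table)
print(fit.report())
print()
print(depth.summarize_depth_bands(table, depth_cutoff=200.0).to_string())

# A negative slope with a small p-value and a modest adjusted R-squared
# means deeper-living species carry measurably fewer distinct opsin
# transcripts, though depth explains only part of the variation.
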