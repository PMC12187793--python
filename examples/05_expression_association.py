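"""Does methylation change track expression change?

Compares TPM between conditions within stoichiometry strata, then
correlates per-site methylation log2FC with transcript expression
log2FC and classifies sites into quadrants.
"""

from m5cscope.association import bin_expression_compare, methylation_expression_correlation
from m5cscope.diffmeth import differential_table
from m5cscope.filtering import filter_sites
from m5cscope.simulate import SimConfig, simulate_bundle

bundle = simulate_bundle(SimConfig(seed=1))
high = {cond: filter_sites(bundle.sites[cond][0])[0] for cond in ("WT", "KO")}

bins = bin_expression_compare(
    high["WT"], high["KO"], bundle.expression["WT"], bundle.expression["KO"]
)
print(bins.round(3).to_string(index=False))
# One row per stoichiometry stratum; the tier column flags strata where
# TPM distributions differ between conditions (* p<0.05, ** p<0.01).

diff = differential_table(high["WT"], high["KO"], "WT", "KO")
corr = methylation_expression_correlation(
    diff, bundle.expression["WT"], bundle.expression["KO"]
)
print(f"\nPearson r = {corr.r:.3f} (p = {corr.p:.3g}, n = {corr.n})")
print(f"quadrants: {corr.quadrants}  on-axis: {corr.n_on_axis}")
# A weakly positive r means hypermethylated sites tend to sit on
# overexpressed transcripts (the hyper_over / hypo_under diagonal).
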