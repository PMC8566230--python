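"""Differential pathway activation between phenotype groups.

One pathway carries a planted +1 log2 activation shift in the "poor
response" group; eight null pathways do not.  PAL is the role-weighted
mean of log2 case-to-normal ratios; groups are compared by unpaired t-test
with BH correction.
"""

from nbgf.matrix import quantile_normalize
from nbgf.pal import differential_pal
from nbgf.simulate import PathwaySpec, SyntheticConfig, generate_pathway_db

base = SyntheticConfig(n_samples=60, n_genes=120, de_genes_per_cluster=0)
genes = base.gene_names()
specs = [
    PathwaySpec(
        "EPO_LIKE",
        {**{g: 1.0 for g in genes[:6]}, **{g: -1.0 for g in genes[6:10]}},
        shift_log2=1.0,
    )
] + [
    PathwaySpec(
        f"NULL_{k}",
        {g: (1.0 if i % 2 == 0 else -0.5)
         for i, g in enumerate(genes[10 + 10 * k : 20 + 10 * k])},
    )
    for k in range(8)
]
cfg = SyntheticConfig(
    n_samples=60, n_genes=120, de_genes_per_cluster=0,
    pathway_specs=tuple(specs), seed=5,
)
pathways, poor_response, expr = generate_pathway_db(cfg)

result = differential_pal(quantile_normalize(expr), poor_response, pathways)
print("pathway activation, poor vs good responders:")
print(result[["pathway", "pal_diff", "t", "p", "q"]].round(4).to_string(index=False))
# pal_diff > 0 means the pathway is more active in poor responders.  The
# planted pathway stands out with a shift near the planted 1.0 log2 unit;
# null pathways occasionally reach small q because the differential-gene
# prefilter favors genes with chance group differences, but their PAL
# shifts stay small and unstable across seeds.
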