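"""Transposable-element composition of simulated lncRNAs by localization.

ERVL-MaLR insertions are planted twice as often in free cytoplasmic
transcripts as in polysomal ones; the per-class mean coverage matrix, the
rank test and the hypergeometric presence test should all recover that
asymmetry.
"""

from polysomeloc import repeats, simulate
from polysomeloc.config import SimulationConfig

config = SimulationConfig(
    n_lncrna_genes=400, n_coding_genes=0, transcripts_per_gene_max=1, seed=11,
    class_proportions={"free_cytoplasmic": 0.5, "light_polysomal": 0.5,
                       "heavy_polysomal": 0.0, "nuclear_specific": 0.0,
                       "not_present": 0.0},
)
bundle = simulate.generate_annotation(config)
profiles = repeats.te_profiles(bundle.transcripts, bundle.repeats)
classes = bundle.truth.transcripts.reset_index()[["transcript_id", "true_class"]]
classes = classes.rename(columns={"true_class": "loc_class"})

matrix = repeats.class_te_matrix(profiles, classes, bundle.transcripts)
print("mean fractional exonic coverage (localization class x repeat class):")
print(matrix.round(4).to_string())

truth = bundle.truth.transcripts
cov = (profiles[profiles["repeat_class"] == "ERVL-MaLR"]
       .set_index("transcript_id")["coverage"].reindex(truth.index).fillna(0.0))
free = cov[truth["true_class"] == "free_cytoplasmic"]
poly = cov[truth["true_class"] == "light_polysomal"]
test = repeats.coverage_rank_test(free, poly)
print(f"\nERVL-MaLR coverage, free vs polysomal: means {test['mean_a']:.4f} vs "
      f"{test['mean_b']:.4f}, rank-test p = {test['p_value']:.2e}")
p = repeats.presence_enrichment(set(free.index), set(cov.index),
                                set(cov.index[cov > 0]))
print(f"hypergeometric presence enrichment in free class: p = {p:.2e}")
print("Small p-values: the planted twofold insertion-rate bias is detected.")
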