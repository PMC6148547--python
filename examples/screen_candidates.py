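"""Screen candidate target genes: DEG test, >=5-of-12 database vote
filter, and their intersection.

With a planted |log2FC| of 3 the screen should recover nearly all planted
DE genes, and the candidate set is the overlap between DEGs and voted
targets — the gene pool every downstream network stage works on.
"""

from mirkey import SyntheticConfig, de_test, intersect_candidates, vote_filter
from mirkey.synthetic import gen_target_votes, gen_tumor_normal_matrix

cfg = SyntheticConfig(seed=42)
study, truth = gen_tumor_normal_matrix(cfg)
votes, _ = gen_target_votes(cfg)

degs = de_test(study)
selected = degs[degs["selected"]]
print(f"DEGs: {len(selected)} of {len(degs)} genes "
      f"({(selected['direction'] == 'up').sum()} up, "
      f"{(selected['direction'] == 'down').sum()} down)")
recall = len(set(selected.index) & set(truth.de_genes)) / len(truth.de_genes)
print(f"planted-DE recall: {recall:.2%}")

predicted = vote_filter(votes, min_db=5)
print(f"predicted targets (>=5 of 12 database votes): {len(predicted)}")

candidates, venn = intersect_candidates(degs, predicted)
print(f"candidates (DEG ∩ predicted): {venn.both} "
      f"(DEG-only {venn.deg_only}, predicted-only {venn.predicted_only})")
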