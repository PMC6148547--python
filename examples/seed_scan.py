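"""Scan 3'UTRs for perfect 2-8 seed matches and classify AU-rich
elements.

Positive UTRs carry planted sites (reverse complement of miRNA positions
2-8, in AU-rich windows); the scanner should report exactly those
offsets and nothing on the negative UTRs.
"""

from mirkey import SyntheticConfig, classify_are, seed_sequence, seed_sites
from mirkey.synthetic import gen_sequences

cfg = SyntheticConfig(seed=42)
mirna, utrs, truth = gen_sequences(cfg)
print(f"miRNA {mirna}")
print(f"seed site to find on UTRs (rev-comp of positions 2-8): "
      f"{seed_sequence(mirna)}\n")

for rec in utrs:
    hits = seed_sites(mirna, rec.sequence, rec.utr_id)
    are = classify_are(rec.sequence, rec.utr_id)
    offs = [h.start for h in hits]
    print(f"{rec.utr_id}: sites at {offs} (planted {list(rec.planted_offsets)}), "
          f"site AU fraction "
          f"{[round(h.au_fraction, 2) for h in hits]}, "
          f"ARE class {are.are_class} ({are.n_auuua} AUUUA)")
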