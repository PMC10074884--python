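"""Curate a raw gene set into train/validation/test partitions.

Applies the full curation pipeline — minimum-length filter, redundancy
clustering at 90% identity, CAI ranking, 70/10/20 split — to a synthetic
gene set and prints the curation log.
"""

from codonoptim import (
    GeneLengthSpec,
    make_host,
    sample_genes,
    usage_from_sequences,
)
from codonoptim.curation import CurationConfig, curate

host = make_host(seed=3, context_order=0, bias_strength=0.5)
genes = sample_genes(host, 120, GeneLengthSpec(60, 200), seed=4)
# inject near-duplicates so clustering has something to remove
genes += [
    type(g)(id=g.id + "_dup", nt_seq=g.nt_seq) for g in genes[:10]
]

usage = usage_from_sequences(genes)
config = CurationConfig(
    min_aa_length=90, identity_threshold=0.90, top_n=80, seed=0
)
result = curate(genes, usage, config=config)

log = result.log
print(log["partition"].value_counts().to_string())
print()
print("first rows of the curation log:")
print(log.head(8).to_string())
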