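"""Encode protein feature spans as BIOES tags and merge the long tail.

A motif spanning residues 3-7 of a toy sequence is encoded as
B/I/I/I/E, a single-residue motif as S, and everything else as O.  A
synthetic long-tailed annotation corpus then shows rare categories
being merged into the sentinel "Other" before encoding.
"""

from otfrm import (
    AnnotatedSequence,
    Span,
    decode_bioes,
    encode_bioes,
    generate_annotated_corpus,
    merge_long_tail,
)

seq = AnnotatedSequence(
    sequence="MKSSLSAQW",
    entities=[Span(3, 7, "Motif1", "motif"), Span(9, 9, "Motif3", "motif")],
)
tags = encode_bioes(seq)["motif"]
for i, (residue, tag) in enumerate(zip(seq.sequence, tags), start=1):
    print(f"  {i:2d} {residue} {tag}")
recovered = decode_bioes(tags, "motif")
print(f"decoded spans: {[(s.start, s.end, s.category) for s in recovered]}")

# long-tail merging on a synthetic corpus
seqs, counts = generate_annotated_corpus(300, n_categories=40, zipf_exponent=2.0, seed=17)
vocab = merge_long_tail(counts, min_count=10)
n_merged = len(vocab.merged)
print(
    f"\ncorpus: {len(counts)} categories seen; {n_merged} rare ones merged into 'Other'"
    f" ({len(vocab.categories)} retained, threshold 10 occurrences)"
)
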