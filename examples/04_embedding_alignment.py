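"""Embedding-substitution-matrix alignment of two related sequences.

With the context-free one-hot mock encoder, substitution scores are 1 for
identical residues and 0 otherwise, so the aligner behaves like classic
NW/SW with match=1, mismatch=0 and a linear gap penalty. A real per-residue
language-model embedding plugs in through the same interface.
"""

from plmhomology import EncoderSpec, MockEncoder, ProteinRecord, substitution_matrix
from plmhomology.align import align_global, align_local, format_alignment

q = ProteinRecord("query", "MKTAYIAKQRQISFVKSHFSRQ")
t = ProteinRecord("target", "MKTAYIAKQRRQISFVKHFSRQ")  # one insertion, one deletion

encoder = MockEncoder(EncoderSpec(dimension=32, noise=0.0))
S = substitution_matrix(encoder.encode(q), encoder.encode(t))

for mode, fn in (("global", align_global), ("local", align_local)):
    result = format_alignment(
        fn(S, gap=0.5, query_id=q.id, target_id=t.id), q.sequence, t.sequence
    )
    print(f"{mode} alignment score = {result.score:.1f} "
          f"({len(result.pairs)} aligned residue pairs)")
    print(f"  {result.query_aligned}")
    print(f"  {result.target_aligned}")
print("the score is the summed substitution (dot-product) score minus 0.5 per gap")
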