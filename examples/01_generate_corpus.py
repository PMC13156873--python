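"""Generate a synthetic labeled screening corpus and summarize it.

A screening corpus is a list of citations (title + abstract) with a binary
relevance label.  The generator draws a rare relevant class whose word
usage is partially separable from the background, mimicking the structure
of real systematic-review benchmarks.
"""

from screenstop import SyntheticSpec, corpus_summary, generate_corpus, write_corpus

spec = SyntheticSpec(
    N=1000,             # records in the corpus
    prevalence_pct=2.0, # 2% of records are relevant
    separability=0.8,   # how distinct the relevant class's vocabulary is
    hard_fraction=0.1,  # share of relevants indistinguishable from background
    seed=7,
    name="demo",
)
corpus = generate_corpus(spec)
n, r, prevalence = corpus_summary(corpus)
print(f"N={n} records, R={r} relevant, prevalence={prevalence}%")
# prevalence is R/N as a percentage: the needle-in-haystack rate the
# screening simulation has to cope with.

path = write_corpus(corpus, "demo_corpus.csv")
print(f"wrote {path} (delimited text; read back with read_labeled_corpus)")
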