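# cid-rpcnn

Document-level **chemical-induced-disease (CID) relation extraction** from
annotated biomedical abstracts, built around a recurrent piecewise
convolutional neural network with class-attention pooling and
knowledge-base feature fusion.

Adverse drug reactions are reported at the *document* level: an abstract
asserts that chemical *c* induces disease *d*, but the evidence is scattered
over several mentions of each entity, often in different sentences.  The
pipeline here targets exactly that setting, for anyone working with
PubTator-annotated corpora such as the BioCreative V CDR benchmark:

1. **Candidate generation** — all mention pairs of a document are grouped by
   their MeSH identifiers into ⟨chemical id, disease id⟩ candidates; each
   candidate is a bag of mention-pair *instances*.
2. **Instance encoding** — each instance is the marked-up token window
   `S₋₁ ⟨ENTC⟩c⟨/ENTC⟩ S₀ ⟨ENTD⟩d⟨/ENTD⟩ S₁` (sentence-bounded context
   before/after, full between-context even across sentences), with word
   embeddings (d_w = 30) and two relative-position embeddings (5 + 5).
3. **Piecewise convolution with attention pooling** — filter banks at widths
   3 and 4 (150 filters each) produce feature maps F; attention scores
   G = Fᵀ M W^classes are softmax-normalised over positions per relation
   class, and each segment S₋₁/S₀/S₁ is pooled as max_j (F A)_{t,j},
   giving a 3 × 150 × 2 = 900-dimensional instance vector.
4. **Multi-instance recurrence** — an LSTM (150 hidden units) consumes a
   candidate's instance vectors in descending between-context length; its
   final hidden state h_m is the document-level candidate representation.
5. **Knowledge fusion and scoring** — binary membership flags of the pair in
   chemical–disease resources (CTD, MEDI, SIDER, MeSH hierarchy) are
   densified to 120 units by one tanh layer and concatenated with h_m; a
   single sigmoid unit yields P(related) = σ(u·v′).

Evaluation is the document-level protocol: predicted-positive
(pmid, chem id, dis id) triples compared as a set against gold, reported as
precision / recall / F percentages.

The network, including reverse-mode differentiation, is implemented in
numpy (`cid_rpcnn.autodiff`), trains with Adam + binary cross-entropy on a
single CPU, and is seed-deterministic end to end.  A synthetic corpus
generator (`cid_rpcnn.synthetic`) emulates the structure of an annotated
corpus — typed mentions with MeSH-style identifiers, planted trigger-word
relations, correlated knowledge tables — so the whole pipeline is testable
without any download.

## Worked example

The classic terbutaline / preterm-labor abstract ships as a fixture:

```python
from cid_rpcnn import generate_worked_example, generate_candidates, build_instance

doc = generate_worked_example()
for c in generate_candidates(doc):
    print(f"<{c.chem_id}, {c.dis_id}>  instances={len(c.instances)}  label={c.label}")

inst = build_instance(doc, doc.mentions[4], doc.mentions[5])
print("S-1:", " ".join(inst.s_before))
print("S0: ", " ".join(inst.s_between), "  S1:", " ".join(inst.s_after))
```

```
<D013726, D002318>  instances=4  label=0
<D013726, D007752>  instances=4  label=1
S-1: Severe cardiovascular complications occurred in eight of 160 patients treated with
S0:  for   S1: .
```

Two chemical mentions (one identifier) × four disease mentions (two
identifiers) collapse into two document-level candidates with four instances
each; only ⟨terbutaline, preterm labor⟩ is a gold CID relation.  The second
block shows the three input segments of one instance: eleven tokens of
sentence context before the chemical, "for" between the entities, and the
sentence-final period after the disease.

Training on a synthetic corpus, end to end:

```python
from cid_rpcnn import (SynthConfig, generate_corpus, generate_candidates,
                       corpus_tokens, encode_instances, random_embeddings)
from cid_rpcnn.model import ModelConfig
from cid_rpcnn.train import TrainConfig, train, predict, evaluate

docs, tables = generate_corpus(SynthConfig(n_docs=200, seed=7))
by_doc = [generate_candidates(d) for d in docs]
train_c = [c for g in by_doc[:160] for c in g]
test_c  = [c for g in by_doc[160:] for c in g]
vocab = random_embeddings(corpus_tokens(train_c + test_c), d_w=30, seed=0)
encode_instances(train_c + test_c, vocab)

params, log = train(train_c, vocab, ModelConfig(seed=0), TrainConfig(seed=0), tables)
res = evaluate(predict(test_c, params, ModelConfig(seed=0), kb_tables=tables), docs[160:])
print(f"held-out: P={res.precision:.2f} R={res.recall:.2f} F={res.f:.2f}")
```

```
held-out: P=100.00 R=100.00 F=100.00
```

The planted relation rule (a trigger word in the between-context of a true
pair) is fully learnable, so a correctly wired model recovers it exactly on
held-out documents; see `docs/methods.md` for what this does and does not
demonstrate about real corpora.

## Command line

```bash
cid-rpcnn synth --out data/ --seed 1          # corpus.pubtator + kb/*.tsv
cid-rpcnn generate --input data/corpus.pubtator --out candidates.jsonl
cid-rpcnn train --corpus data/corpus.pubtator --kb-dir data/kb --out model.npz
cid-rpcnn predict --corpus data/corpus.pubtator --checkpoint model.npz \
                  --kb-dir data/kb --out preds.tsv
cid-rpcnn evaluate --gold data/corpus.pubtator --predictions preds.tsv
cid-rpcnn ablate --train-corpus train.pubtator --test-corpus test.pubtator \
                 --kb-dir data/kb                 # the model-variant family
```

`predict` writes positive predictions as PubTator relation lines
(`PMID<TAB>CID<TAB>chem<TAB>dis`), so `evaluate` consumes the same format as
the gold corpus.  Real corpora in PubTator format (e.g. BioCreative V CDR)
drop in directly for `train`/`predict`/`evaluate`.

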