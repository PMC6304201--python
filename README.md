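# neutrosim

Similarity measures for neutrosophic sets, with a similarity-ranking
diagnosis classifier.

A *neutrosophic* evaluation scores each criterion with three independent
degrees — truth T, indeterminacy I and falsity F — constrained only by
0 ≤ T, I, F ≤ 1 and T + I + F ≤ 3, so "probably yes", "unsure" and
"probably no" evidence can coexist.  `neutrosim` implements both the
single-valued flavour (SVNS: T, I, F are numbers) and the interval-valued
one (IVNS: each membership is a closed subinterval of [0, 1]), and the
similarity measures used to compare such evaluations in multi-criteria
decision support — most prominently medical diagnosis, where a patient's
symptom profile is matched against canonical diagnosis profiles and the
argmax of the similarity scores is the decision.

It is intended for researchers and practitioners in fuzzy multi-criteria
decision analysis who need reference implementations of these measures,
their axiom checks, and the classic five-diagnosis benchmark.

## The measures

For SVNS profiles N₁, N₂ over criteria x₁…xₙ, with Δ denoting a
componentwise difference:

| id | form |
|----|------|
| `s1` | min/max overlap Σmin(T,I,F-components)/Σmax(…) |
| `s2` | mean per-criterion cosine of the (T, I, F) vectors |
| `s1_star` | ½·(S₁ + 1 − D) |
| `s2_star` | ½·(S₂ + 1 − D) |
| `sm` | 1 − D |
| `sd` | 1/(1 + D) |
| `sc1` | mean cos(π·max(\|ΔT\|,\|ΔI\|,\|ΔF\|)/2) |
| `sc2` | mean cos(π·(\|ΔT\|+\|ΔI\|+\|ΔF\|)/6) |
| `sy` | SC/(SC + D) |

where D is the normalized Euclidean distance
√(Σᵢ(ΔTᵢ² + ΔIᵢ² + ΔFᵢ²)/3n) (pooled convention) or the mean over
criteria of the per-criterion distances (per-item convention, the
default — see `docs/methods.md` for why).  The interval-valued
counterparts apply the same recipes to the six interval bounds.

The plain cosine `s2` is **not** a genuine similarity measure: any two
proportional but unequal membership vectors score exactly 1.  The hybrid
measures `s1_star`/`s2_star` average an overlap or cosine term with the
distance complement, which restores the axiom *S = 1 ⇔ equality* while
keeping range [0, 1] and symmetry.  The `check-axioms` engine verifies
all of this empirically on seeded random profiles and constructs
explicit proportional counterexamples for the cosine.

## Worked example

Patient P1 (fever 〈0.8, 0.2, 0.1〉, headache 〈0.6, 0.3, 0.1〉, stomach
pain 〈0.2, 0.1, 0.8〉, cough 〈0.6, 0.5, 0.1〉, chest pain 〈0.1, 0.4, 0.6〉)
against the bundled five-diagnosis knowledge base:

```python
from neutrosim import NeutrosophicClassifier, load_fixture, rank_diagnoses

p1 = load_fixture("p1")
table1 = load_fixture("table1")
print(rank_diagnoses(p1, table1, measure="s2_star").to_text())
```

prints

```
measure=s2_star convention=per_item
  1. Q2  0.837781 <- winner
  2. Q1  0.815575
  3. Q3  0.800600
  4. Q4  0.549963
  5. Q5  0.488082
```

so P1 is classified as malaria (Q2): its symptom profile is closest to
the malaria row under the cosine–distance hybrid; 0.8378 is the
similarity on the [0, 1] scale.  Every implemented measure agrees on Q2
for this patient.  The same thing through the scikit-learn estimator
surface (which composes with sklearn pipelines and model selection):

```python
clf = NeutrosophicClassifier(measure="s1_star").fit(table1)
clf.predict([p1])          # array(['Q2'], dtype='<U2')
```

The CLI mirrors the library:

```bash
neutrosim diagnose patient.csv table.csv --measure s2_star
neutrosim similarity a.csv b.csv --measure sc1
neutrosim check-axioms --measure s2 --samples 1000 --seed 7
neutrosim reproduce-tables
```

`reproduce-tables` recomputes every cell of the four reference score
tables for the bundled benchmark, prints the recomputed value, the
published value and their delta, and classifies each cell as exact,
truncated-in-the-last-decimal, or a source erratum (a published value
that does not follow from the published data — several distance-based
rows of the reference tables are internally inconsistent; the command
reports them rather than emulating them).

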