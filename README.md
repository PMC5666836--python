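# phytamyloid

Proteome-wide screening for potentially amyloidogenic proteins.

Amyloids are protein fibrils with cross-β architecture; the propensity of a
protein to form them is driven by short amyloidogenic regions (ARs) and by
compositionally biased regions (CBRs) rich in Q/N or E. `phytamyloid`
implements both detection routes as a reusable pipeline for whole proteomes
(it was designed around plant proteome screens, where seed storage proteins
and membrane transporters turn out to be hotspots), together with the
downstream statistics such screens report:

- **AR scanning** — sliding-window scoring with a pluggable
  position-specific scoring matrix (PSSM): every window `w` of length `W`
  scores `S(w) = Σ_j M[j, w_j]`; windows with `S ≥ T` are merged into
  maximal regions and regions shorter than 10 residues are discarded.
- **CBR detection** — for a residue class `C` with background frequency
  `p`, a candidate stretch of length `L` containing `k` class members is
  scored by the binomial upper tail `P(X ≥ k), X ~ Bin(L, p)`; disjoint
  stretches with tail `< 10⁻⁸` are called greedily (lowest probability
  first), anchored on class members.
- **Proteome statistics** — flagged fractions, residue coverage,
  region-length medians/modes, organellar subsets, and cross-species
  comparison by two-sided Fisher's exact test with Benjamini–Hochberg
  adjustment.
- **Term enrichment** — one-sided hypergeometric over-representation of
  flagged proteins per GO term (reported at p < 0.01 with ≥ 5 interest
  proteins), with species × term heat-map matrix export.
- **Feature overlap** — fraction of each feature type (transmembrane,
  signal peptide, domains, unannotated) covered by predicted regions, and
  the distribution of ARs over CBR classes.
- **PFAM summary** — abundance of PFAM families among seed storage
  proteins (GO:0045735), counting Q/N-rich members per family and species.
- **Synthetic proteomes** — a seeded generator planting CBR segments of
  controlled purity/length and PSSM-positive stretches, plus annotation
  tables with planted enrichment, so every stage is testable with known
  truth.

## Worked example

```python
from phytamyloid import (
    ProteinRecord, ResidueClass, ScoringMatrix, find_cbrs, predict_ars,
    log_binomial_tail,
)

# CBR route: a pure Q-run of 7 in an A background, class QN at background 0.05
rec = ProteinRecord("demo", "A" * 50 + "Q" * 7 + "A" * 50)
qn = ResidueClass.from_letters("QN", background_p=0.05)
print(find_cbrs(rec, qn))
# [Region(start=50, end=57, kind='CBR', residue_class='QN',
#         score=-9.107209969647867)]

print(log_binomial_tail(6, 6, 0.05))
# -7.806179973983887   (a 6-run: tail 1.5625e-8 >= 1e-8, so it is NOT called)

# AR route: an indicator PSSM scoring 1 per Q, window 6, threshold 4
matrix = ScoringMatrix.indicator("Q", window_length=6, threshold=4.0)
print(predict_ars(ProteinRecord("demo2", "Q" * 12 + "A" * 20), matrix))
# [Region(start=0, end=14, kind='AR', residue_class='', score=6.0)]
```

The CBR score is the log10 tail probability: the 7-residue Q-run has tail
`0.05⁷ ≈ 7.8e-10 < 10⁻⁸`, so it is called, and one residue fewer already
fails the threshold. The AR call spans [0, 14) because windows starting at
positions 7 and 8 (scores 5 and 4) are still at or above the threshold and
merge into the pure-Q run.

A full screen runs from a YAML config or the CLI:

```bash
phytamyloid scan-ar  --fasta proteome.fasta --matrix waltz_ph7.tsv --out ar.tsv
phytamyloid scan-cbr --fasta proteome.fasta --classes QN,E --out cbr.tsv
phytamyloid run      --config run.yaml
```

Note the actual trained PSSM weights (e.g. the Waltz matrix) are input
data, not part of this package; any matrix in the documented TSV format
(`W <int> T <float>` header, then one row of per-position scores per
residue) can be supplied.

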