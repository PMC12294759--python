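# frbinn

Pathway-masked neural classification of inflammatory-disease transcriptomes,
with a full interpretability stack.

Some chronic inflammatory diseases (ulcerative colitis, Crohn's disease,
NASH, chronic hepatitis B) carry a substantially elevated cancer risk, while
others (asthma, psoriasis, rheumatoid arthritis, IBS, Alzheimer's disease)
do not. `frbinn` implements, end to end, a framework for studying this
divergence from bulk expression data:

1. **An epidemiological categorization rule.** A disease is *cancer-prone*
   (CP-CID) iff any published effect size exceeds its threshold:

   `prone ⇔ (RR > 2) ∨ (HR > 2) ∨ (SIR > 1.4)`

   with RR the relative risk, HR the hazard ratio and SIR the standardized
   incidence ratio. A nine-disease registry of published values ships with
   the package and splits 5 NCP / 4 CP.

2. **A biologically informed neural network (BINN).** A sparse MLP over the
   four classes {cancer, CP-CID, NCP-CID, normal} whose hidden connectivity
   is dictated by a gene → pathway → superpathway hierarchy via binary
   masks: layer *l* computes `h^{l+1} = f((S^l ⊙ W^l) h^l + b^l)`, so a
   weight exists only where the prior says a relation does. Dense softmax
   head, cross-entropy loss, Adam (defaults: 500 epochs, batch 32, lr 1e-3),
   stratified 5-fold CV with weighted precision/recall/F1. Implemented in
   NumPy with its own reverse- and forward-mode gradients.

3. **Attribution.** Three methods against a trained model, all attributing a
   chosen class's logit from a zero baseline with m = 800 steps/queries:
   Integrated Gradients `IG_i = (x_i − x'_i) ∫₀¹ ∂F(x' + α(x − x'))/∂x_i dα`
   (right-Riemann or Gauss–Legendre quadrature); conductance, the share of
   that integral flowing through each hidden (pathway) neuron; and Kernel
   SHAP, Shapley values via kernel-weighted linear regression over feature
   coalitions with the efficiency constraint enforced exactly. Attribution
   uses only correctly predicted samples, each against its true class.

4. **Consistency analysis.** Gene rankings by mean |attribution|, composite
   scores across methods, top-k intersection fractions between methods and
   between disease categories, top-5% selection, and a pluggable keep/drop
   gene-filter hook.

5. **A synthetic cohort generator** producing four-class TPM-like expression
   with disjoint planted discriminative gene sets per non-normal class under
   a known hierarchy, so the whole workflow is testable without downloads.

## Worked example

```bash
python examples/build_and_train.py
```

```
cohort: 200 samples x 40 genes, 10 pathways, 5 superpathways
masked parameters: 89 (dense equivalent: 489)
5-fold weighted precision 0.980, recall 0.980, F1 0.980
```

The hierarchy mask cuts the parameter count about fivefold, and the masked
network still separates the four synthetic classes nearly perfectly
(chance level 0.25). Attribution then recovers what the model learned:

```bash
python examples/attribute_and_rank.py
```

```
IG: 4/6 planted CP genes in the top 6
SV: 4/6 planted CP genes in the top 6
IG-vs-SHAP top-5 intersection fraction: 1.00
IG-vs-SHAP top-10 intersection fraction: 1.00
composite top-5% selection (2 genes): ['g08', 'g05']
```

Both attribution methods put mostly planted CP-CID genes at the head of the
ranking and agree perfectly on the top 10 — the inter-method consistency
the framework relies on. `examples/classify_diseases.py` prints the
nine-disease categorization and `examples/pathway_conductance.py` shows
conductance concentrating on the pathways that actually host planted signal.

A command-line front end mirrors the workflow:

```bash
frbinn simulate --out cohort/
frbinn train --expr cohort/expression.tsv --labels cohort/labels.tsv \
             --gmt cohort/gene_sets.gmt --edges cohort/edges.tsv --out model.npz
frbinn attribute --model model.npz --expr cohort/expression.tsv \
                 --labels cohort/labels.tsv --method ig --class cp --out ig_cp.csv
frbinn classify-risk --registry diseases.tsv --out categories.tsv
frbinn run --seed 1 --out run/          # the whole pipeline + manifest
```

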