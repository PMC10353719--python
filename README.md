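# sidcor

Signed distance correlation and partial distance correlation for
data-driven correlation networks in omics tables (metabolomics,
lipidomics, or any samples × features matrix).

Pearson and Spearman correlations only see linear or monotonic trends.
Distance correlation (dCor) is a non-parametric dependence measure that is
zero **only** under full independence, so it also detects quadratic,
sinusoidal, circular and other non-linear relationships between features —
exactly the kind of structure metabolic regulation produces. `sidcor`
computes, for a numeric table with samples as rows and features as columns:

* **one-to-one** — signed dCor for every feature pair, with Pearson and
  Spearman companions and t-based p-values;
* **one-to-all** — dCor between each feature and the joint Euclidean
  distance structure of all remaining features;
* **partial** — Gaussian-graphical-model partial correlations from the
  Moore–Penrose pseudo-inverse of the distance-covariance matrix, with
  Fisher-z p-values, separating direct from indirect associations.

## The statistic

For a feature *X* observed in *n* samples, build the Euclidean distance
matrix *a<sub>jk</sub>* = |x<sub>j</sub> − x<sub>k</sub>| and doubly center
it: *A<sub>jk</sub>* = *a<sub>jk</sub>* − ā<sub>j·</sub> − ā<sub>·k</sub> + ā<sub>··</sub>.
With *B* the same construction for *Y*:

    dCov²(X,Y) = (1/n²) Σ_jk A_jk B_jk        dVar(X) = dCov²(X,X)
    dCor(X,Y)  = dCov(X,Y) / √(dVar(X)·dVar(Y)) ∈ [0, 1]

Because dCor is non-negative, directionality is restored by attaching the
sign of the Pearson correlation of the same pair ("signed dCor").
Significance uses t = dCor·√(n−2)/√(1−dCor²) against a t distribution with
n−2 df. For partial mode, Σ<sub>ij</sub> = dCov(X<sub>i</sub>,X<sub>j</sub>)
is pseudo-inverted to ω and ρ<sub>ij·rest</sub> = −ω<sub>ij</sub>/√(ω<sub>ii</sub>ω<sub>jj</sub>);
p-values come from z = arctanh(ρ) with p = 2(1 − Φ(|z|·√(N−M−1))).

Input tables are automatically z-scored per feature. Missing values are a
hard error naming every offending cell (impute upstream first); constant
features are excluded with a warning. See `docs/methods.md` for all
modelling choices and caveats.

## Worked example

Simulate a 30-sample, 4-feature first-order Markov chain
(X1→X2→X3→X4, adjacent correlation 0.7) and build its network:

```sh
sidcor simulate --scenario gaussian_chain --n 30 --m 4 --seed 7 --output chain.csv
sidcor run --mode one-to-one --input chain.csv --output edges.csv \
           --dcor-threshold 0.3 --p-threshold 0.05
```

`edges.csv` (descending |dCor|):

```
feature_a,feature_b,dcor,sign,signed_dcor,p_dcor,...
X3,X4,0.7237103146535988,1,0.7237103146535988,6.19700467853735e-06,...
X1,X2,0.6819131684392896,1,0.6819131684392896,3.3286390273612214e-05,...
X2,X3,0.593898019758292,1,0.593898019758292,0.0005402145600504091,...
X1,X4,0.5614207079002056,1,0.5614207079002056,0.0012467900429769855,...
X1,X3,0.5121967356284671,1,0.5121967356284671,0.0038085228657201986,...
X2,X4,0.3987089963403249,1,0.3987089963403249,0.029077568265487744,...
```

All six pairs correlate marginally — the chain transmits dependence through
its middle nodes. Partial mode removes that indirect signal:

```sh
sidcor run --mode partial --input chain.csv --output partial.csv
```

```
feature_a,feature_b,partial_rho,z,p_partial,mode
X3,X4,0.65538981342296,0.7846889563239273,8.729177960322172e-05,partial
X1,X2,0.5973227983807944,0.6889745016609252,0.0005713287984116639,partial
X2,X3,0.472968861804035,0.5138878221888419,0.01018632910894893,partial
X1,X4,0.42153698040225984,0.4495596629274454,0.02458905339741223,partial
X2,X4,-0.29253219906311534,-0.30133320043416856,0.1318962901662927,partial
X1,X3,-0.15149151571030686,-0.1526666337068523,0.4452647257923693,partial
```

The three adjacent (true) edges stay strong and significant while the
indirect pairs (X1,X3), (X2,X4) collapse toward zero — the partial route
recovers the chain topology. Everything is also available as a library
(`sidcor.dcor_pair`, `sidcor.one_to_all`, `sidcor.fit_partial`,
`sidcor.run`), and `--format xlsx` writes the same tables as a spreadsheet.

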