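# mibci — filter-bank CSP classification for motor-imagery EEG

`mibci` implements the classic two-class motor-imagery (MI) brain–computer
interface pipeline: band-pass decomposition of epoched EEG into the mu
(8–13 Hz), low-beta (13–22 Hz), high-beta (22–30 Hz) and full 8–30 Hz bands,
Common Spatial Pattern (CSP) feature extraction per band, feature ranking by
five selectors — Relief-F, Inf-FS, ILFS, FSV and Statistical Dependency (SD)
— and classification with LDA, RBF-kernel SVM or a small MLP, evaluated by
stratified 5-fold cross-validation with accuracy, F1 and AUROC.

It is written for BCI researchers who want a tested, leakage-safe reference
implementation of this pipeline that runs end-to-end on synthetic data with
known ground truth, and that can also load BCI Competition III-style
recordings (`cnt`/`mrk`/`nfo` MATLAB layout) when the user supplies them.

## The method

For trials $E$ of class $c$, CSP averages the trace-normalized spatial
covariances $C_c = \langle EE^\top/\mathrm{tr}(EE^\top)\rangle$, whitens the
composite $C_\mathrm{c} = C_1 + C_2$ with $P$ (so $P C_\mathrm{c} P^\top = I$),
and rotates by the eigenvectors $B$ of the whitened class-1 covariance,
giving filters $W = P^\top B$ that simultaneously diagonalize both class
covariances with complementary eigenvalues $D_1 + D_2 = I$. Per trial the
feature for filter $w_j$ is $f_j = \log \mathrm{var}(w_j^\top E)$; the $k$
filters from each end of the spectrum are kept ($2k$ features per band, so
four bands with $k=4$ give a 32-dimensional vector, and $k=1$ on a 2-channel
montage gives 8).

The selectors rank those features: Relief-F by nearest-hit/nearest-miss
feature differences with exponential rank decay; Inf-FS and ILFS by total
damped path energy $\left[((I-rA)^{-1}-I)\,\mathbf{1}\right]_i$ through a
feature-similarity graph (Inf-FS builds $A$ from dispersion and Spearman
correlation, ILFS learns it from quantized feature/label statistics); FSV
from the weights of a successively linearized concave-minimization margin
program; SD by $\sum_{y,z} p(y,z)^2/(p(y)p(z))$ over equal-frequency
quantization bins, which equals 1 exactly under independence.

## Worked example

```python
from mibci import MotorImageryCSP, SynthConfig, make_synthetic_mi

epochs, truth = make_synthetic_mi(SynthConfig(seed=7))   # 60 trials/class, 8 ch
model = MotorImageryCSP(epochs, selector="relieff", n_features=16, classifier="lda")
res = model.fit(seed=42)
print(res.summary())
```

The default generator plants a strong (variance ratio 8) band-limited
covariance difference, which the pipeline recovers perfectly:

```
 accuracy: 100.0000 +/- 0.0000
       f1:   1.0000 +/- 0.0000
    auroc:   1.0000 +/- 0.0000
top-ranked features: 31(full#7), 24(full#0), 8(low_beta#0), ...
```

Accuracy is percent correct on held-out folds, F1 treats class 2 as
positive, and AUROC is the probability a class-2 trial outscores a class-1
trial. The top-ranked features are the extreme CSP filters of the full and
beta bands — exactly where the planted effect lives. In a hard regime
(variance ratio 1.4, noise SD 2.0, 40 trials/class) the same call prints
`accuracy: 58.7500 +/- 11.3537`, `auroc: 0.6687 +/- 0.0947`: the pipeline
degrades gracefully toward chance instead of overfitting, because CSP,
scaler, selector and classifier are all refitted inside each training fold.

The same pipeline is scriptable:

```bash
mibci run --config config.yaml --out-dir out/   # synth -> CSP -> rank -> CV report
mibci rank --epochs out/epochs --method relieff --out ranking.csv
```

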