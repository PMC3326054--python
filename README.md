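# amplimit

Detection limits and abundance-cutoff selection for low-complexity 16S
amplicon surveys.

When a microbial community is profiled by amplicon sequencing at a few
hundred reads per sample, taxa below a depth-dependent abundance are simply
not expected to show up — and conversely, low-abundance observations are as
likely to be reagent contaminants as real community members.  `amplimit` is
for researchers who need to answer, quantitatively: *how many reads does it
take to see a taxon at abundance p?* and *below what relative abundance
should an observed OTU be treated as suspect at my sequencing depth?*  It was
built around the kind of low-complexity communities found in respiratory
samples (e.g. bronchoalveolar lavage), where a single organism can make up
75% of the community and the taxa of clinical interest span five orders of
magnitude in abundance.

## The model

Under independent sampling of reads, the number of reads until a taxon of
relative abundance *p* is first observed is geometric, so the probability of
detecting it at least once in *k* reads is

```
F(k; p) = 1 − (1 − p)^k
```

Two closed forms follow:

- **depth needed** for detection with confidence *c*:
  `N_c(p) = ⌈ln(1 − c) / ln(1 − p)⌉` (the 95th percentile of the detection
  depth for c = 0.95), and
- **minimum detectable abundance** at a fixed depth *k*:
  `p*(k) = 1 − (1 − c)^(1/k)`, which doubles as an empirical
  relative-abundance cutoff for screening likely-spurious OTUs.

At a normalization depth of 900 reads, `p*(900) ≈ 0.33%` (reported as 0.3%);
at 400 reads, `p*(400) ≈ 0.75%`.

The package validates this model against *empirical* detection probabilities
obtained by multiple rarefaction — repeatedly subsampling a deep simulated
library without replacement and recording how often each taxon appears at
each depth — and scores the agreement with a bootstrapped Kolmogorov–Smirnov
statistic.  The deep libraries come from a built-in simulator of a
twelve-strain mock community (nine genera, abundances from 75% down to
0.00075%) with 16S copy-number bias, normal read lengths (250 ± 50 bp,
trimmed to 230), homopolymer-length noise and a linear 5′→3′
substitution/indel error ramp.  Downstream, tables can be rarefied,
filtered at `p*(depth)`, screened for contaminant genera, and compared with
weighted UniFrac, Shannon diversity, an exact Mann–Whitney U test, PERMANOVA
and PCoA.

## Worked example

```python
import amplimit as am

spec = am.mock_community()                      # 12 taxa, 9 genera
lib = am.simulate_library(spec, 20_000, seed=7, copy_number_bias=False)
print("dominant fraction: %.4f" % lib.fractions()["P_aeruginosa"])

for depth in (900, 400):
    p_star = am.min_detectable_abundance(depth)
    print(f"depth {depth}: min detectable abundance {100*p_star:.2f}%")

print("reads for 95% detection at p=0.00075:", am.reads_required(0.00075))
print("P(detect p=0.00075 in 900 reads) = %.3f"
      % am.geometric_detection_cdf(0.00075, 900))

curves = am.multiple_rarefaction(lib.counts, levels=[10, 100, 1000, 10000],
                                 n_subsamples=100, seed=1)
cur = {c.taxon_id: c for c in curves}["M_catarrhalis"]
model = am.GeometricDetectionModel(p=spec.abundances["M_catarrhalis"])
d, pv = am.bootstrap_ks_test(cur, model, seed=2)
print("KS D=%.3f p=%.3f" % (d, pv))
```

prints

```
dominant fraction: 0.7510
depth 900: min detectable abundance 0.33%
depth 400: min detectable abundance 0.75%
reads for 95% detection at p=0.00075: 3993
P(detect p=0.00075 in 900 reads) = 0.491
KS D=0.013 p=0.887
```

Reading the numbers: the simulated library reproduces the 75% dominant
specification to sampling error; at 900 reads the detection-limit cutoff is
0.33% of reads, so the three rarest genera in the mock community
(abundances ≤ 0.075%) fall below the 95% confidence limit — a genus at
0.075% abundance needs ~4,000 reads for reliable detection and has only a
49% chance of appearing at all among 900 reads.  The bootstrap KS p-value of
0.89 says the empirical detection curve for *M. catarrhalis* is fully
consistent with the geometric model.

`examples/` contains one narrative script per capability (simulation,
detection limits, contamination filtering, reproducibility comparison); each
prints its results with a line of interpretation.  A thin CLI wraps the same
functions, e.g.:

```
amplimit threshold --depth 900
amplimit simulate --n-reads 5000 --seed 1 --out sim/
amplimit run --seed 1 --out report/
```

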