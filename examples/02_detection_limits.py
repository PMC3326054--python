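"""Detection limits: rarefaction curves, the geometric model, and cutoffs.

Simulates a deep (50,000-read) unbiased mock library, estimates each taxon's
empirical detection probability by multiple rarefaction, tests the fit of
the geometric model with a bootstrapped Kolmogorov-Smirnov statistic, and
derives depth and abundance cutoffs.
"""

from amplimit import (
    GeometricDetectionModel,
    bootstrap_ks_test,
    default_levels,
    geometric_detection_cdf,
    min_detectable_abundance,
    mock_community,
    multiple_rarefaction,
    reads_required,
    simulate_library,
)

spec = mock_community()
lib = simulate_library(spec, 50_000, seed=2, copy_number_bias=False)

levels = default_levels(lib.size)
curves = multiple_rarefaction(lib.counts, levels, n_subsamples=100, seed=3)

print(f"{'taxon':<16}{'abundance':>11}{'N95':>9}{'KS D':>8}{'KS p':>8}")
for curve in sorted(curves, key=lambda c: spec.abundances[c.taxon_id],
                    reverse=True):
    p = spec.abundances[curve.taxon_id]
    n95 = reads_required(p)
    if any(0 < f < 1 for f in curve.proportions):
        d, pv = bootstrap_ks_test(curve, GeometricDetectionModel(p=p), seed=4)
        print(f"{curve.taxon_id:<16}{p:>11.6f}{n95:>9}{d:>8.3f}{pv:>8.3f}")
    else:
        print(f"{curve.taxon_id:<16}{p:>11.6f}{n95:>9}{'-':>8}{'-':>8}")

print()
for depth in (900, 400):
    print(f"minimum detectable abundance at {depth} reads: "
          f"{100 * min_detectable_abundance(depth):.2f}%")
print(f"P(detect a 0.075%-abundance genus in 900 reads) = "
      f"{geometric_detection_cdf(0.00075, 900):.2f}")

print()
print("N95 is the depth needed to detect each taxon with 95% confidence;")
print("large KS p-values mean the empirical curves are consistent with the")
print("geometric model, which justifies using its closed-form cutoffs.")
print("The rarest taxa get small p-values for a structural reason: at")
print("subsample depths approaching the library size, sampling without")
print("replacement detects a taxon faster than the geometric (with-")
print("replacement) approximation predicts.")
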