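"""Score classification and localization results.

Shows the confusion-matrix metrics in both conventions and the boundary
error summary across several cases.
"""

from pyloruskit import ConfusionCounts, location_error, metrics

# e.g. 1979 intestinal (positive) and 1822 stomach frames, a few mistakes
counts = ConfusionCounts(p_t=1969, n_t=1800, p_f=10, n_f=22)
for convention in ("printed", "standard"):
    m = metrics(counts, convention)
    print(f"{convention:8s}: accuracy={m.accuracy:.4f} "
          f"sensitivity={m.sensitivity:.4f} specificity={m.specificity:.4f}")

err = location_error(estimates=[4852, 5420, 1660, 2044], truths=[4849, 5440, 1634, 2042])
print(f"per-case errors: {err.per_video_errors}")
print(f"mean error {err.mean_error:.1f} frames, median {err.median_error:.1f} frames")
# The median is reported alongside the mean because one poorly localized
# case inflates the mean while the median stays at the typical error.
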