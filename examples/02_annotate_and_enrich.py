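"""Peak calling, genomic-feature annotation and shuffle-null enrichment.

Calls peaks from one sample's fragments, classifies every peak by the
genomic feature at its centre, and compares the observed class counts to
the mean over 1000 width-matched random placements ("observed/random").
A ratio far above 1 with a small empirical p means the peaks concentrate in
that feature class beyond chance.
"""

from ocratlas.annotate import annotate_peaks, call_peaks_simple, feature_distribution, relative_enrichment
from ocratlas.synth import SynthConfig, simulate_study

study = simulate_study(SynthConfig(seed=1))
sizes = study.annotation.chrom_sizes

frags = study.fragments[("Y", 1)]
peaks = call_peaks_simple(frags, sizes, sample="Y_1")
print(f"called {len(peaks)} peaks from {len(frags)} fragments")

ann = annotate_peaks(peaks, study.annotation)
print("\nfeature distribution (% of peaks):")
print(feature_distribution(ann).round(2).to_string())

enr = relative_enrichment(peaks.intervals, study.annotation, sizes,
                          n_shuffles=1000, seed=1)
print("\nobserved/random enrichment (1000 shuffles):")
print(enr[["observed", "expected", "ratio", "p_empirical"]].round(3).to_string())
print("\npromoter classes sit far above ratio 1: the landscape planted half "
      "of all peaks within 1 kb of a TSS.")
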