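"""Build fraction-of-overlap features for a few hand-made domains.

The feature value for a domain and a track is the summed overlap in bp with
every instance of the track, divided by the domain length — so a 100-bp
domain with 15 bp of CHD1 binding scores 0.15, and mutually overlapping
instances can push the fraction above 1.
"""

from domainlen import (
    GenomicInterval,
    IntervalTrack,
    build_feature_matrix,
    fraction_of_overlap,
)

domain = GenomicInterval("chr1", 0, 100, name="promoter_domain")
chd1 = IntervalTrack("CHD1", [GenomicInterval("chr1", 85, 115)])
print(f"single 15-bp overlap on a 100-bp domain -> {fraction_of_overlap(domain, chd1)}")

# two instances overlapping each other inside the domain: the sum rule
# counts both, so the fraction exceeds the union coverage (30 bp -> 0.30)
stacked = IntervalTrack("TF_x", [GenomicInterval("chr1", 10, 30),
                                 GenomicInterval("chr1", 20, 40)])
print(f"two stacked 20-bp instances -> {fraction_of_overlap(domain, stacked)}")

domains = IntervalTrack("domains", [
    domain, GenomicInterval("chr1", 500, 1500, name="broad_domain")])
matrix = build_feature_matrix(domains, [chd1, stacked])
print("\nfeature matrix (rows = domains, cols = tracks):")
print(matrix.to_frame().to_string(index=False))
print("\nEach row pairs a domain's length target (bp) with its overlap "
      "fractions; this table is the regression input.")
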