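"""Keep records shared by a given percentage of samples.

A cohort table has one row per (locus, sample). Variants present in most
samples are likely common polymorphisms or systematic artifacts; variants
private to one sample are candidate de-novo events. The sample-presence
filter selects either side of that split.
"""

from genotab import SampleSpec, filter_by_sample_presence, make_table

rows = [
    ["chr1:100", "S1", "0/1"], ["chr1:100", "S2", "0/1"],
    ["chr1:100", "S3", "1/1"],
    ["chr2:55", "S1", "0/1"], ["chr2:55", "S2", "0/1"],
    ["chr7:9", "S3", "0/1"],
]
cohort = make_table(["locus", "sample", "genotype"], rows, "cohort.tsv")

shared = filter_by_sample_presence(
    cohort, SampleSpec(sample_columns=["sample"], identity_columns=["locus"],
                       threshold=0.66))
private = filter_by_sample_presence(
    cohort, SampleSpec(sample_columns=["sample"], identity_columns=["locus"],
                       threshold=0.34, direction="at_most"))

print(f"cohort: {cohort.n_rows} rows, 3 observed samples")
print("loci in >= 66% of samples:",
      sorted(set(shared["locus"].values)))
print("loci in <= 34% of samples:",
      sorted(set(private["locus"].values)))
print("\nchr1:100 is carried by 3/3 samples (presence 1.0), chr2:55 by 2/3 "
      "(0.67), chr7:9 by 1/3 (0.33).")
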