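"""Window tiling, fragment counting, relH CpG-enrichment QC and
full-quantile normalization on a hand-made toy dataset.

relH compares the CpG density of the immunoprecipitated fragments to the
genome average: values well above 1 (the study used > 2.0) indicate that
the methylated-DNA pulldown worked.
"""

import numpy as np
import pandas as pd

import medipdmr as m
from medipdmr.windows import WindowCountMatrix

# a 6 kb toy genome with a CpG-rich first kilobase
rng = np.random.default_rng(0)
dense = "".join(rng.choice(list("ACGT"), 1000, p=[0.15, 0.35, 0.35, 0.15]))
rest = "".join(rng.choice(list("ACGT"), 5000, p=[0.35, 0.15, 0.15, 0.35]))
genome = {"chr1": dense + rest}

windows = m.tile_windows({"chr1": 6000}, width=300)
print(f"{len(windows)} windows of 300 bp")

# fragments concentrated on the CpG-rich kilobase, as MeDIP would produce
starts = np.sort(rng.integers(0, 900, 60))
fragments = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 120})
score, passes = m.relh_score(fragments, genome)
print(f"relH = {score:.2f} (QC pass at > 2.0: {passes})")

samples = pd.DataFrame({"sample_id": ["a", "b"], "group": ["Hi", "Lo"],
                        "gender": ["F", "F"], "ip_batch": [1, 1]})
counts = m.count_fragments({"a": fragments, "b": fragments.iloc[:30]},
                           windows, samples)
kept = m.filter_windows(counts, min_count=5, min_fraction=0.5)
print(f"{counts.n_windows} windows counted, {kept.n_windows} pass the "
      "count filter (> 5 in at least half of the samples)")

norm = m.quantile_normalize(kept)
# tied counts receive averaged quantile values, so compare column totals
print("after full-quantile normalization the sample columns share the same "
      "total signal:",
      np.allclose(norm.normalized[:, 0].sum(), norm.normalized[:, 1].sum()))
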