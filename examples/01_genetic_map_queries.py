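"""Genetic-map queries: point rates, cumulative cM, and genetic distances.

Builds a tiny three-anchor map in the HapMap table convention and shows the
three primitive queries every downstream statistic is made of.
"""

import numpy as np

from g4recomb import GeneticMap, genome_average_rate

# rate 1.0 cM/Mb on [100, 1100), 3.0 on [1100, 2100)
gmap = GeneticMap(
    chromosome="1",
    positions=np.array([100, 1100, 2100]),
    rates=np.array([1.0, 3.0, 0.0]),
    cum_cm=np.array([0.0, 0.001, 0.004]),
)

print("rate at 600:", gmap.rate_at(600), "cM/Mb")          # inside first interval
print("rate at 1100:", gmap.rate_at(1100), "cM/Mb")        # left-closed boundary
print("cm at 600:", gmap.cm_at(600), "cM")                 # 1.0 cM/Mb x 500 bp
print("distance 600-1600:", gmap.genetic_distance(600, 1600), "cM")
print("genome average:", genome_average_rate({"1": gmap}), "cM/Mb")

# The distance crosses an anchor: 500 bp at 1.0 plus 500 bp at 3.0 cM/Mb
# = 0.002 cM, and the genome average is total cM / total Mb = 2.0 cM/Mb.
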