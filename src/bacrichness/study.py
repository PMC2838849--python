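"""Published scalar inputs of the kuruma shrimp BAC screening study.

These are the printed numbers the headline analysis consumes — screen sizes,
library parameters, and hybridization totals for the MjBL2 library and the
Mj024A04 reference segment.  They are inputs, not expected outputs: the
`reproduce` pipeline recomputes every derived quantity from them.
"""

from __future__ import annotations

from .librarystats import LibraryParams

# microsatellite genotyping screen of F/M/R-positive clones (plates 001-008)
N_CLONES_GENOTYPED = 342
K_DISTINCT_GENOTYPES = 299

# MjBL2 library
LIBRARY = LibraryParams(
    n_clones=49_152,          # 128 plates x 384 wells
    mean_insert_kb=135.0,
    genome_size_mbp=2_000.0,  # penaeid shrimp genome size
    n_individuals=13,         # source animals pooled into the library
)
N_CLONES_GENOTYPING_SUBSET = 3_072  # plates 001-008: 8 x 384 wells

# colony hybridization against the F, M, R probes
HYB_POSITIVE = 200
HYB_TOTAL = 381

# telomeric-repeat (GGTTA) colony-hybridization positive rates, percent
GGTTA_RATE_FMR_POSITIVE = 45.4
GGTTA_RATE_ALL = 17.1

REFERENCE_LENGTH_BP = 120_000
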