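#!/usr/bin/env python
"""Generate the synthetic study inputs every later step consumes.

Draws a 99-person two-cohort genotype/phenotype set from the published
12-haplotype spectrum (null hemoglobin effects) and a Balding-Nichols
three-population allele-frequency table with a drifted focal population,
then writes them with checksums under results/fixtures/.
"""

import json
from pathlib import Path

from haploscan import write_fixture_set

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"
SEED = 20161201  # study-visit date as the run seed

manifest = write_fixture_set(OUT, seed=SEED)
print(f"wrote fixture set to {OUT} (seed {SEED}):")
for name, digest in manifest["files"].items():
    print(f"  {name}  sha256:{digest[:12]}")
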