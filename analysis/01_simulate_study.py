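#!/usr/bin/env python
"""Generate the synthetic two-breed chip study used by the downstream
analysis scripts.

Writes a phased, ancestral-allele-annotated VCF for two populations that
split from a common Wright-Fisher ancestor (a selective sweep acts in
population 1 only), plus the popmap, gene models (one spanning the sweep
core), a Table-3-shaped litter-size CSV, and the full simulation truth.

Output: results/bundle/
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from popscan.synthetic_data import BundleConfig, make_fixture_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "bundle"


def main():
    config = BundleConfig()  # the study defaults: 2 x 40 samples, 5000 SNPs
    paths = make_fixture_bundle(config, seed=20231, out_dir=OUT, force=True)
    print(f"simulated study written to {OUT}")
    for key, path in paths.items():
        print(f"  {key:8s} {path.name}  ({path.stat().st_size // 1024} KiB)")
    print(
        f"sweep: chromosome {config.sweep_chrom} @ {config.sweep_position:,} bp "
        f"-> derived frequency {config.sweep_final_freq} in population 1"
    )


if __name__ == "__main__":
    main()
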