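#!/usr/bin/env python
"""Generate the default synthetic ECM root-tip dataset.

181 absorbance spectra with the study's sample composition (five fungal
species across mono-specific beech, mixed deciduous and Swabian sites),
written as a wide CSV + metadata sidecar.  The full spectra table is a few
MB, so it goes to scratch/; a small composition summary lands in results/.
"""

from collections import Counter
from pathlib import Path

import ectospec as es

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = es.GeneratorConfig()
    ds = es.generate_dataset(cfg)

    out = ROOT / "scratch" / "synthetic"
    out.mkdir(parents=True, exist_ok=True)
    es.write_dataset(ds, out / "spectra.csv", out / "spectra.meta.csv")

    counts = Counter(
        (s.meta.species, s.meta.site, s.meta.forest_type) for s in ds
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with (results / "composition_summary.csv").open("w") as fh:
        fh.write("species,site,forest_type,n\n")
        for (species, site, ft), n in sorted(counts.items()):
            fh.write(f"{species},{site},{ft},{n}\n")

    print(f"wrote {len(ds)} spectra (seed {cfg.seed}) to {out}")
    by_species = Counter(s.meta.species for s in ds)
    for species, n in sorted(by_species.items()):
        print(f"  {species:24s} n={n}")


if __name__ == "__main__":
    main()
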