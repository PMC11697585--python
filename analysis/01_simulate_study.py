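#!/usr/bin/env python
"""Generate the synthetic 21-day study.

Writes daily multi-echo GRE and DWI volumes, the shared label volume and
lookup table, bvals/bvecs and the study manifest under scratch/study/
(binary imaging data stays out of results/).  Two of the 21 days (12 and 16)
are migraine days; the generative condition effects are +1.0 1/s in the left
caudate, -1.1 1/s in the right caudate, +1.3 / -1.0 1/s in the ventral
diencephalon, +0.4 1/s isotropic in left cerebral WM and a 17% reduction of
the right-WM anisotropic amplitude.
"""

import argparse
from pathlib import Path

from qrelax.phantom import PhantomSpec, generate_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "study")
    args = parser.parse_args()

    spec = PhantomSpec(seed=args.seed)
    manifest = generate_study(spec, args.out)
    n_mig = sum(d["condition"] == "migraine" for d in manifest["days"])
    print(f"wrote {len(manifest['days'])} days ({n_mig} migraine) to {args.out}")
    print(f"regions: {sorted({(b.name, b.hemisphere) for b in spec.region_layout.values()})}")


if __name__ == "__main__":
    main()
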