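#!/usr/bin/env python
"""Volume calibration for the shipped cavity designs.

The composite volume of each design is a calibration target, not an
emergent quantity: the default dimensions in ``pulptherm.geometry`` were
chosen with this script so that, at 0.125 mm resolution, direct access
lands on 12.2 mm^3, occlusal-distal on 29.35 mm^3, and the two slots within
1 mm^3 of each other.  Cavity planes are kept on the 0.25 mm lattice of the
crown bounding box so measured volumes agree across the 0.25 / 0.125 mm
resolutions.

Modes:
  report          measure the shipped defaults against the targets (default)
  sweep KIND DIM  sweep one dimension of one design over lattice values and
                  print the volume at each step

Usage:
  python scripts/calibrate_volumes.py
  python scripts/calibrate_volumes.py sweep direct_access width_y
"""

from __future__ import annotations

import argparse
import json

import numpy as np

import pulptherm as pt

TARGETS = {"direct_access": 12.2, "occlusal_distal": 29.35}
SLOT_PAIR_TOLERANCE_MM3 = 1.0


def measure(intact, kind, **overrides):
    design = pt.CavityDesign.default(kind, **overrides)
    restored = pt.carve_and_fill(intact, design)
    return pt.region_volume(restored, "composite")


def report(resolutions=(0.25, 0.125)):
    out = {}
    for h in resolutions:
        intact = pt.build_phantom(pt.PhantomParams(voxel_size=h))
        out[h] = {kind: measure(intact, kind) for kind in pt.DESIGN_KINDS}
    payload = {"volumes_mm3": out, "targets_mm3": TARGETS, "checks": {}}
    fine = out[min(resolutions)]
    for kind, target in TARGETS.items():
        payload["checks"][f"{kind}_within_2pct"] = bool(
            abs(fine[kind] - target) / target <= 0.02)
    payload["checks"]["slot_pair_within_1mm3"] = bool(
        abs(fine["vertical_slot"] - fine["horizontal_slot"])
        <= SLOT_PAIR_TOLERANCE_MM3)
    print(json.dumps(payload, indent=2))


def sweep(kind, dim, span=1.0, step=0.25, voxel=0.125):
    intact = pt.build_phantom(pt.PhantomParams(voxel_size=voxel))
    base = pt.CavityDesign.default(kind).dims[dim]
    for value in np.arange(base - span, base + span + step / 2, step):
        try:
            v = measure(intact, kind, **{dim: round(float(value), 4)})
            print(f"{dim}={value:6.2f}  volume={v:8.3f} mm^3")
        except pt.PulpthermError as exc:
            print(f"{dim}={value:6.2f}  rejected: {exc}")


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    sub = parser.add_subparsers(dest="mode")
    sub.add_parser("report")
    p_sweep = sub.add_parser("sweep")
    p_sweep.add_argument("kind", choices=pt.DESIGN_KINDS)
    p_sweep.add_argument("dim")
    p_sweep.add_argument("--span", type=float, default=1.0)
    p_sweep.add_argument("--step", type=float, default=0.25)
    args = parser.parse_args()
    if args.mode == "sweep":
        sweep(args.kind, args.dim, args.span, args.step)
    else:
        report()


if __name__ == "__main__":
    main()
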