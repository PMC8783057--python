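"""Fingers opening/closing kinetics of the KF-DNA binary complex.

Runs the full pipeline (simulate -> detect -> segment) on the extensible
and dideoxy-terminated binary-complex scenarios, extracts fingers-open and
fingers-closed dwells from the maximum-evidence HMM decodings, and fits
exit rates with the quantisation-exact geometric MLE (2-frame dead time).
Also reports the opening-rate fold change between the two substrates and
the implied activation-energy difference attributed to the 3'-OH contact.

Run:  python analysis/02_binary_complex_rates.py [--molecules 300] [--seed 21]
"""

import argparse
import dataclasses
import json
from pathlib import Path

import polfret as pf
from polfret.pipeline import HmmConfig, segment_traceset


def measure(scheme, phys, n_molecules, duration, seed):
    traces, _paths = pf.simulate_experiment(scheme, phys, n_molecules, duration, seed=seed)
    events_by_mol = {}
    for tr in traces:
        thr = pf.adaptive_threshold(tr)
        events_by_mol[tr.molecule_id] = pf.detect_events(
            tr, thr, exclude_before=phys.red_laser_window
        )
    _models, dwells_by_event = segment_traceset(
        traces, events_by_mol, HmmConfig(n_restarts=3), seed=seed + 1
    )
    dwells = [d for dw in dwells_by_event.values() for d in dw]
    out = {}
    for label, key in (("open", "k_close"), ("closed", "k_open")):
        est = pf.fit_geometric_rate(
            dwells, frame_dt=phys.frame_dt, n_min=2, state_label=label,
            n_boot=300, seed=seed + 2,
        )
        out[key] = dataclasses.asdict(est)
    return out


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--molecules", type=int, default=300)
    ap.add_argument("--duration", type=float, default=60.0)
    ap.add_argument("--seed", type=int, default=21)
    ap.add_argument("--out", default="results/binary_complex_rates.json")
    args = ap.parse_args()

    phys = pf.PhotophysicsModel(
        acceptor_bleach_rate=0.0, donor_bleach_rate=0.0,
        label_fractions={"dual": 1.0, "donor_only": 0.0, "acceptor_only": 0.0, "unlabelled": 0.0},
    )
    cfgs = pf.make_demo_configs()
    results = {}
    for name in ("binary_extensible", "binary_dideoxy"):
        scheme = cfgs[name].scheme
        results[name] = measure(scheme, phys, args.molecules, args.duration, args.seed)
        r = results[name]
        print(f"{name}: k_close = {r['k_close']['rate']:.2f} ± {r['k_close']['stderr']:.2f} /s, "
              f"k_open = {r['k_open']['rate']:.2f} ± {r['k_open']['stderr']:.2f} /s")

    k_oh = results["binary_extensible"]["k_open"]["rate"]
    k_dd = results["binary_dideoxy"]["k_open"]["rate"]
    results["opening_fold_change"] = k_dd / k_oh
    results["delta_E_kcal_per_mol"] = pf.arrhenius_delta_e(k_dd, k_oh, 298.0)
    print(f"opening-rate fold change (dideoxy / 3'-OH): {k_dd / k_oh:.1f}")
    print(f"implied ddG from 3'-OH contact: {results['delta_E_kcal_per_mol']:.2f} kcal/mol")

    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    Path(args.out).write_text(json.dumps(results, indent=1))
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
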