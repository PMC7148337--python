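#!/usr/bin/env python
"""Functional validation of the assembled models.

Runs the metabolite-conversion and reaction-optimisation battery against the
translated reference and both reconstructions, and writes per-model summary
tables (results/validation_<model>.tsv).
"""

import argparse
from pathlib import Path

from orthogem.analysis import load_medium
from orthogem.io import load_model
from orthogem.validation import load_test_battery, run_suite, save_suite_summary


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workspace", type=Path, default=Path("results/workspace"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    media = {
        name: load_medium(args.workspace / f"{name}.tsv")
        for name in ("HAM", "RPMI1640")
    }
    tests = load_test_battery(args.workspace / "test_battery.json")
    models = {
        "reference": load_model(args.outdir / "translated_model.json"),
        "minimal": load_model(args.outdir / "model_min.xml"),
        "maximal": load_model(args.outdir / "model_max.xml"),
    }
    for name, model in models.items():
        summary = run_suite(model, tests, media)
        mct, rot = summary["counts"]["MCT"], summary["counts"]["ROT"]
        print(f"{name}: MCT {mct['passed']}/{mct['total']} passed, "
              f"ROT {rot['passed']}/{rot['total']} passed; "
              f"components present in {summary['components_present']['total']} "
              f"tests of which {summary['components_present']['passed']} pass")
        save_suite_summary(summary, tests, args.outdir / f"validation_{name}.tsv")


if __name__ == "__main__":
    main()
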