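"""Train and evaluate the CNN concentration quantifier.

Runs the full pipeline at desk scale (direct 320x256 render, CNN input
80x64), trains the classifier on the 450-image train split, decodes
test-split concentrations by probability-weighted averaging over the
panel, and reports the maximum relative error and the decoded-vs-true
regression line.

Run from the repository root:  python analysis/04_train_quantifier.py
"""

import json
from pathlib import Path

from specklequant.config import load_config
from specklequant.pipeline import run_all

OUT = Path("results")


def main() -> None:
    cfg = load_config(overrides={"seed": 0, "out_dir": str(OUT / "cnn_run")})
    metrics = run_all(cfg)
    OUT.mkdir(exist_ok=True)
    print(json.dumps(
        {k: metrics[k] for k in (
            "counts", "surface_sensitivity", "max_rel_error_pct",
            "mean_rel_error_pct", "slope", "intercept",
            "epochs_run", "final_val_accuracy")},
        indent=2,
    ))
    print(f"\nmax relative decoding error on the {metrics['counts']['test']} "
          f"test images: {metrics['max_rel_error_pct']:.3f}%")
    print(f"decoded-vs-true slope: {metrics['slope']:.5f}")


if __name__ == "__main__":
    main()
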