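"""Render a complete simulated sHsp-client incubation experiment.

Generates a bead registration pair plus dual-channel TIRF stacks for the
alphaB-crystallin + firefly-luciferase preset at four incubation timepoints
(two replicates each), with full ground-truth manifests.  Image stacks are
binary scratch data; the run config is what downstream steps consume.
"""
from pathlib import Path

from smstoich import pipeline, simulate

OUT = Path("scratch/experiment")
SEED = 20260929


def main() -> None:
    acq = simulate.AcquisitionParams(n_frames=300, field_px=(128, 128))
    cfg = pipeline.simulate_dataset(
        OUT,
        seed=SEED,
        preset="aBc-FLUC",
        timepoints_h=[0.0, 0.3, 0.6, 1.0],
        replicates=2,
        n_molecules=40,
        acq=acq,
    )
    n_stacks = 2 * len(cfg.fields)
    print(f"wrote {n_stacks} stacks + bead pair + manifests to {OUT}")
    print(f"config: {OUT / 'config.yaml'} (seed {SEED})")


if __name__ == "__main__":
    main()
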