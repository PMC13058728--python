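#!/usr/bin/env python
"""Generate the synthetic multi-omic study inputs.

Emulates the study design — 3 genotypes (isogenic, P497H, P506T) x 2 media
conditions (CM, GS) x 4 replicates, 2-day heavy pulse — with 200 proteins
(5 planted clients among 20 interactors), a 120-species class-structured
lipidome with internal standards and technical duplicates, a 400-feature
transcript matrix, and the pulldown interactome. Writes every input table
plus ground truth under results/inputs/.
"""

from turnomix.io import RunConfig
from turnomix.simulate import SimulationSpec
from turnomix.pipeline import stage_simulate

SEED = 1
OUT = "results/inputs"


def main() -> None:
    spec = SimulationSpec(seed=SEED)
    paths = stage_simulate(spec, OUT, RunConfig(seed=SEED))
    print(f"study design: {len(spec.design.genotypes)} genotypes x "
          f"{len(spec.design.conditions)} conditions x "
          f"{spec.design.replicates_per_group} replicates, "
          f"{spec.design.pulse_time_days:g}-day heavy pulse")
    print(f"{spec.n_proteins} proteins ({spec.n_planted_clients} planted "
          f"clients among {spec.n_interactors} interactors), "
          f"{spec.n_lipids} lipid species, {spec.n_transcripts} transcripts")
    for name, path in paths.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
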