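"""Generate the synthetic study system.

Builds the default synthetic world: 72 coastal communities across 5
countries with household livelihood surveys (ranked occupations and 16
material items), the 16-run ocean total-consumer-biomass ensemble (1 deg),
20-run crop-yield ensembles for rice/maize/cassava (0.5 deg, cassava
single-model), a coastal population-density grid, and site coordinates.

Writes everything under results/synthetic/.
"""

from pathlib import Path

from coastclim.config import PipelineConfig, SyntheticConfig
from coastclim.pipeline import stage_simulate

OUT = Path("results/synthetic")
SEED = 1

if __name__ == "__main__":
    cfg = PipelineConfig(output_dir=str(OUT), seed=SEED,
                         synthetic=SyntheticConfig(seed=SEED))
    paths = stage_simulate(cfg)
    print("Synthetic study system written:")
    for k, v in paths.items():
        print(f"  {k}: {v}")
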