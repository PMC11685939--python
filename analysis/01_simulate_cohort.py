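"""Generate the default synthetic cohort (40 AML vs 12 HD) for all assay layers.

Writes the sample sheet, SCENITH condition gMFIs, bead panels and lipidome to
results/cohort/, and the (large) per-cell event table to scratch/cohort/.
Downstream steps regenerate any layer deterministically from the same seed,
so the CSVs are for inspection, not a hidden dependency.
"""

from pathlib import Path

from liquidmet import cohort as sc

CONFIG = sc.CohortConfig(seed=1)  # 40 AML / 12 HD, default effects

OUT = Path("results/cohort")
SCRATCH = Path("scratch/cohort")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    meta = sc.cohort_metadata(CONFIG)
    meta.to_csv(OUT / "metadata.csv", index=False)
    sc.simulate_scenith_cohort(CONFIG).to_csv(OUT / "scenith_gmfi.csv", index=False)
    sc.panels_to_csv(sc.simulate_bead_panels(CONFIG), OUT / "bead_panels.csv")
    sc.lipidome_to_csv(sc.simulate_lipidome(CONFIG), OUT / "lipidome.csv",
                       OUT / "lipidome_groups.csv")
    sc.events_to_csv(sc.simulate_redox_cytometry(CONFIG), SCRATCH / "events.csv")
    print(f"cohort: {CONFIG.n_aml} AML + {CONFIG.n_hd} HD samples, seed {CONFIG.seed}")
    print(meta.groupby(["cohort", "eln_risk"]).size())


if __name__ == "__main__":
    main()
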