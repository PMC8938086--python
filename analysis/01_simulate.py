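"""Simulate every input the downstream analyses need.

Writes to results/: the four-arm 100-patient cohort (one lesion per row),
the three-tissue IHC specimen table, and a handful of noisy phantoms with
ground-truth masks.
"""

from pathlib import Path

from sonohcc import io as sio
from sonohcc.synthgen import (
    CohortConfig,
    IHCCohortConfig,
    PhantomConfig,
    cohort_to_frame,
    generate_cohort,
    generate_ihc_cohort,
    generate_phantom,
)

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)

    cohort_cfg = CohortConfig(seed=SEED)
    cohort = cohort_to_frame(generate_cohort(cohort_cfg))
    sio.write_csv(OUT / "cohort.csv", cohort, seed=SEED, config="CohortConfig-defaults")
    n_mal = (cohort["pathology"] == "malignant").sum()
    print(f"cohort: {cohort['patient_id'].nunique()} patients, {len(cohort)} lesions "
          f"({n_mal} malignant / {len(cohort) - n_mal} benign)")
    print(cohort.groupby("group")["patient_id"].nunique().to_string())

    ihc_cfg = IHCCohortConfig(seed=SEED)
    specimens = generate_ihc_cohort(ihc_cfg)
    sio.write_csv(OUT / "ihc_specimens.csv", specimens, seed=SEED, config="IHCCohortConfig-defaults")
    print(f"IHC specimens: {specimens.groupby('group').size().to_dict()}")

    for i in range(5):
        cfg = PhantomConfig(speckle_scale=0.2, impulse_density=0.1, seed=SEED * 1000 + i)
        image, mask = generate_phantom(cfg)
        sio.write_image(OUT / f"phantom_{i:03d}.tif", image)
        sio.write_mask(OUT / f"phantom_{i:03d}_mask.png", mask)
    print("wrote 5 speckle+impulse phantoms with ground-truth masks")


if __name__ == "__main__":
    main()
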