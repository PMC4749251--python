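"""Generate the demo cohort and its phantom volumes.

Draws a 20-subject cohort from the normative covariate/intensity model,
builds one macular phantom spec per subject (layer intensities tied to the
subject's age and image quality), renders an example volume, and records the
cohort ground truth under results/.

Volumes themselves are bulky and reproducible from the seed, so only one
example TIFF goes to scratch/; downstream scripts re-render on the fly.
"""

from pathlib import Path

from octmac.cohort import CohortModel, generate_cohort, phantom_spec_for_subject
from octmac.io import write_surfaces, write_volume
from octmac.phantom import PhantomSpec, generate_phantom

SEED = 20260927
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main():
    RESULTS.mkdir(exist_ok=True)
    (SCRATCH / "volumes").mkdir(parents=True, exist_ok=True)
    model = CohortModel()
    cohort = generate_cohort(model, 20, seed=SEED)
    cohort.to_csv(RESULTS / "demo_cohort_truth.csv", index=False)

    base = PhantomSpec()
    row = cohort.iloc[0]
    spec = phantom_spec_for_subject(base, row)
    vol, truth = generate_phantom(spec, seed=SEED + 1, subject_id=row.subject_id)
    write_volume(vol, SCRATCH / "volumes" / f"{row.subject_id}.tiff")
    write_surfaces(truth.z, SCRATCH / "volumes" / f"{row.subject_id}_truth.csv")

    print(f"cohort of {len(cohort)} subjects written to {RESULTS / 'demo_cohort_truth.csv'}")
    print(f"ages {cohort.age.min():.0f}-{cohort.age.max():.0f} "
          f"(mean {cohort.age.mean():.1f}), imageQ mean {cohort.image_q.mean():.1f}")
    print(f"example volume {vol.shape} -> {SCRATCH / 'volumes'}")


if __name__ == "__main__":
    main()
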