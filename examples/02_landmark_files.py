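"""Write and read landmark annotation files.

Serializes a small phantom cohort to the CSV dialect (one landmark per row)
and reads it back, then measures every vertebra.
"""

import tempfile
from pathlib import Path

from spinetorsion import (
    PhantomParams,
    generate_phantom,
    measure_collection,
    read_landmarks,
    write_landmarks,
)

cohort = [
    generate_phantom(
        PhantomParams(theta_post_deg=theta, tau_deg=tau, noise_sigma_mm=0.3, seed=i),
        subject_id=f"S{i + 1}",
    )
    for i, (theta, tau) in enumerate([(5.0, 4.0), (12.0, 7.5), (2.0, 3.0)])
]

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "landmarks.csv"
    write_landmarks(cohort, path)
    print(path.read_text().splitlines()[0])  # the schema header
    back = read_landmarks(path)
    table = measure_collection(back)

print(table.round(1).to_string(index=False))
print()
print("Each row is one vertebra: alpha/beta are the posterior and anterior")
print("component rotations (deg, right positive); torsion is their difference.")
print("The 0.3 mm annotation noise shifts each angle by about a degree.")
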