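"""Generate a synthetic health-checkup cohort with known ground truth.

The generator emulates a lab-test EHR extract: a patient × clinotype
matrix with sex-specific reference ranges, a latent linear dependency
(Hemoglobin tracks Hematocrit), one disease that elevates Glucose, and
10% missing values.  Every number below is reproducible from the seed.
"""

from cpa import DiseaseSpec, GeneratorConfig, LatentModel, generate_cohort

config = GeneratorConfig(
    n_patients=1000,
    latent=LatentModel(
        coefficients={"Hemoglobin": {"Hematocrit": 0.8}},
        noise_sd={"Hemoglobin": 0.6},
    ),
    diseases=[DiseaseSpec("E11", prevalence=0.1, effects={"Glucose": 1.5})],
    missing_rate=0.10,
    seed=42,
)
matrix, patients, diagnoses, truth = generate_cohort(config)

print(matrix)
print(f"patients by sex: {patients['sex'].value_counts().to_dict()}")
print(f"diagnosis records (E11): {len(diagnoses)}")
diseased = sorted({d.patient_id for d in diagnoses})
controls = matrix.patients.difference(diseased)
gap = (
    matrix.values.loc[diseased, "Glucose"].mean()
    - matrix.values.loc[controls, "Glucose"].mean()
)
print(f"Glucose gap, diseased vs rest: {gap:.2f} mmol/L (planted: 1.5 sd x 0.6 = 0.9)")
print(
    "Hematocrit range for a female patient:",
    tuple(
        matrix.ref_low.loc[patients["sex"] == "female", "Hematocrit"].iloc[:1].tolist()
        + matrix.ref_high.loc[patients["sex"] == "female", "Hematocrit"].iloc[:1].tolist()
    ),
)
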