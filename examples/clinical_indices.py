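"""Clinical indices used when validating adipocyte size against metabolism.

HOMA-IR estimates insulin resistance from fasting insulin and glucose;
VAI is a sex-specific composite of waist circumference, BMI,
triglycerides and HDL-cholesterol that tracks visceral adiposity.
"""

from adiposizer import ClinicalRecord, homa_ir, vai

patients = [
    ("P1", ClinicalRecord("male", waist_circumference=135.0, bmi=49.0, tg=1.64, hdl=1.18,
                          fasting_insulin=25.0, fasting_glucose=4.5)),
    ("P2", ClinicalRecord("female", waist_circumference=118.0, bmi=44.0, tg=1.20, hdl=1.45,
                          fasting_insulin=10.0, fasting_glucose=5.4)),
]

for pid, rec in patients:
    h = homa_ir(rec.fasting_insulin, rec.fasting_glucose)
    v = vai(rec)
    print(f"{pid} ({rec.sex:6s}): HOMA-IR = {h:.2f}   VAI = {v:.2f}")

# HOMA-IR above ~2.5 suggests insulin resistance; VAI rises with waist
# circumference and triglycerides and falls with HDL.
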