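"""Blood-gas chemistry primitives: saturation, contents, shunt and Fick.

Builds arterial blood for a moderate-ARDS patient, derives mixed venous
blood from the Fick principle at fixed cardiac output, and measures the
venous admixture of a 30% shunt mixture.
"""

from alveosim import (MetabolicParams, make_blood_sample, o2_saturation,
                      shunt_fraction, venous_from_fick)

met = MetabolicParams(hb=10.5, co=11.1, vo2=294.3, rq=0.6, fio2=0.8)

art = make_blood_sample(po2=153.7, pco2=44.0, hb=met.hb)
print(f"arterial: PO2 {art.po2:.1f} mmHg, SO2 {art.so2:.3f}, "
      f"CaO2 {art.o2_content:.2f} ml/dl")

ven = venous_from_fick(art, met)
print(f"mixed venous (Fick, CO {met.co} l/min, VO2 {met.vo2} ml/min): "
      f"PvO2 {ven.po2:.1f} mmHg, CvO2 {ven.o2_content:.2f} ml/dl")
print(f"  a-v O2 content difference: {art.o2_content - ven.o2_content:.2f} "
      "ml/dl  (= VO2 / (10 CO))")

# a 30% venous admixture of ideal end-capillary blood
cc = make_blood_sample(po2=500.0, pco2=40.0, hb=met.hb)
ca_mixed = 0.7 * cc.o2_content + 0.3 * ven.o2_content
qs = shunt_fraction(cc.o2_content, ca_mixed, ven.o2_content)
print(f"Berggren shunt equation recovers the imposed admixture: "
      f"Qs/Qt = {100 * qs:.1f}%")

print(f"saturation at PO2 100 (PCO2 40, pH 7.4): "
      f"{o2_saturation(100.0):.3f} (standard adult curve)")
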