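"""Foot-process width from electron-microscopy measurement tables.

FPW = (pi/4) x (sum of GBM length / sum of foot-process count), pooled per
group before dividing.  Widened foot processes (effacement) indicate
podocyte injury.
"""

from mirtox import EMMeasurement, foot_process_width

measurements = [
    EMMeasurement(image="i1", glomerulus="g1", animal="control", gbm_length=10.0,
                  foot_process_count=20),
    EMMeasurement(image="i2", glomerulus="g2", animal="control", gbm_length=12.0,
                  foot_process_count=24),
    EMMeasurement(image="i3", glomerulus="g1", animal="treated", gbm_length=10.0,
                  foot_process_count=8),
    EMMeasurement(image="i4", glomerulus="g2", animal="treated", gbm_length=12.0,
                  foot_process_count=10),
]

for animal, width in foot_process_width(measurements, group_by="animal").items():
    print(f"{animal}: FPW = {width:.3f} (length units per foot process)")
print("\nHigher FPW in the treated animal reflects fewer foot processes per "
      "unit of\nglomerular basement membrane, i.e. effacement.")
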