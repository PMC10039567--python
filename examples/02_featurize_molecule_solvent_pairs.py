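"""Turn (molecule, solvent) pairs into fused fingerprint vectors.

The fused ("multi-modal") descriptors stitch two fingerprint families
together — here topological torsions plus daylight-type paths — for the
molecule and again for the solvent, giving one 8192-bit vector per
record.
"""

import numpy as np

from aiegen import SpectralRecord, featurize_record, preset, quantitative_descriptors
from aiegen.featurize import daylight_fp, torsion_fp

tpe = "C(=C(c1ccccc1)c1ccccc1)(c1ccccc1)c1ccccc1"

# quantitative descriptors: 196 physicochemical/graph properties
q = quantitative_descriptors(tpe)
print(f"quantitative descriptor vector: length {len(q)}")

# single fingerprint families
print(f"daylight paths set {int(daylight_fp(tpe).sum())} of 2048 bits")
print(f"torsions set {int(torsion_fp(tpe).sum())} of 2048 bits")

# a full record: molecule blocks then solvent blocks
record = SpectralRecord(tpe, solvent_name="tetrahydrofuran", lambda_abs=308.0)
fv = featurize_record(record, preset("toptorsion-daylight"))
print(f"\nfused vector: length {len(fv.values)}")
for block in fv.layout:
    print(f"  {block.name:15s} offset {block.offset:5d} length {block.length}"
          f"  ({int(fv.values[block.offset:block.offset+block.length].sum())} bits set)")
# The layout is part of the model contract: a trained model refuses
# feature vectors whose block layout differs from its training layout.
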