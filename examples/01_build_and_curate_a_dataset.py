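"""Curate raw multi-peak literature entries into a spectral dataset.

A solvated luminogen is often reported with several absorption and
emission peaks.  Curation keeps one value per target: the
longest-wavelength absorption peak and the highest-intensity emission
peak.  Records are validated and canonicalized so the same molecule
drawn two ways counts once.
"""

from aiegen import Dataset, RawEntry, curate_peaks, summarize

entries = [
    RawEntry(
        "N(c1ccccc1)(c1ccccc1)c1ccc(C=Cc2ccc(C#N)cc2)cc1",  # TPA-vinyl-benzonitrile
        solvent_name="tetrahydrofuran",
        abs_peaks=(310.0, 402.0),
        em_peaks=((505.0, 0.4), (538.0, 1.0)),
    ),
    RawEntry(
        "C(=C(c1ccccc1)c1ccccc1)(c1ccccc1)c1ccccc1",  # tetraphenylethylene
        solvent_name="acetonitrile",
        abs_peaks=(238.0, 308.0),
        em_peaks=((448.0, 1.0),),
    ),
    # same TPE drawn with a different atom order: canonicalization unifies them
    RawEntry(
        "c1ccc(C(=C(c2ccccc2)c2ccccc2)c2ccccc2)cc1",
        solvent_name="dimethyl sulfoxide",
        abs_peaks=(310.0,),
        em_peaks=((465.0, 1.0),),
    ),
]

records = [curate_peaks(e) for e in entries]
ds = Dataset(records=records)

for r in ds:
    print(f"{r.molecule_smiles[:40]:40s} {r.solvent_name:20s} "
          f"abs={r.lambda_abs} nm  em={r.lambda_em} nm")

s = summarize(ds)
print(f"\n{s.n_records} records, {s.n_distinct_molecules} distinct molecules, "
      f"{s.n_distinct_solvents} solvents")
print(f"emission range: {s.lambda_em_range} nm")
# The first entry keeps abs=402 (longest peak) and em=538 (most intense peak);
# the two TPE drawings collapse to one distinct molecule observed in two solvents.
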