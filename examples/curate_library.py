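"""Curate a small hand-built bioassay table.

Shows structure standardization (salt stripping, aromatic perception),
rejection of metal complexes and mixtures, imputation of qualitative
inactives, control normalization and InChIKey deduplication.
"""

from ureascape.curation import RawActivityRecord, curate


def rec(record_id, smiles, value, activity_type="IC50", control=20.0, ref="ref1"):
    return RawActivityRecord(
        record_id=record_id,
        smiles=smiles,
        activity_value=value,
        activity_type=activity_type,
        control_value=control,
        species="Canavalia ensiformis",
        year=2018,
        reference_id=ref,
    )


records = [
    # thiourea-like inhibitor, more potent than the control -> active
    rec("r1", "NC(=S)Nc1ccccc1", 8.0),
    # same structure as a hydrochloride salt, weaker -> merged, potent kept
    rec("r2", "NC(=S)Nc1ccccc1.Cl", 30.0, ref="ref2"),
    # benzoate sodium salt == benzoic acid after stripping
    rec("r3", "O=C([O-])c1ccccc1.[Na+]", 150.0),
    # qualitative "inactive": imputed to 1000 uM before normalization
    rec("r4", "Oc1ccccc1", None, activity_type="qualitative_inactive"),
    # nickel complex and a two-component mixture are rejected with reasons
    rec("r5", "[Ni]([NH3])([NH3])Cl", 5.0),
    rec("r6", "NC(=O)c1ccccc1.OC(=O)c1ccncc1", 5.0),
]

curated, normalized, rejects = curate(records)

print(f"raw records:      {len(records)}")
print(f"curated compounds: {len(curated)}  (r1+r2 merged on InChIKey)")
print(f"rejected records:  {len(rejects)}")
print()
print(curated[["inchikey", "ratio", "activity_class", "n_merged"]].to_string(index=False))
print()
print(rejects[["record_id", "reason"]].to_string(index=False))
print()
print("ratio = IC50 / control; ratio < 1 means more potent than the 20 uM")
print("thiourea control, hence 'active'; the qualitative inactive lands at")
print("ratio 50 (1000/20) and every rejection carries its reason.")
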