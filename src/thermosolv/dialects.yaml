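# Column maps for supported solubility-table dialects (version 1).
#
# Public deposits rename headers between releases; edit or extend these maps
# rather than the reader.  `temperature: null` means the dialect has no
# temperature column and `default_temperature_K` is used for every row.
# `solubility_representation` is one of:
#   log10_molar  - column already holds log10 S in mol/L
#   molar        - column holds S in mol/L (log10 taken at ingestion)
version: 1
dialects:
  native:
    columns:
      solute_smiles: solute_smiles
      solvent_smiles: solvent_smiles
      temperature: temperature_K
      solubility: logS
      source_id: source_id
    temperature_unit: K
    solubility_representation: log10_molar
  bigsoldb:
    columns:
      solute_smiles: SMILES
      solvent_smiles: SMILES_Solvent
      temperature: "T,K"
      solubility: Solubility
      source_id: Source
    temperature_unit: K
    solubility_representation: molar
  solprop:
    columns:
      solute_smiles: solute_smiles
      solvent_smiles: solvent_smiles
      temperature: T
      solubility: logS
      source_id: source
    temperature_unit: K
    solubility_representation: log10_molar
  leeds:
    columns:
      solute_smiles: SMILES
      solvent_smiles: Solvent_SMILES
      temperature: null
      solubility: LogS
      source_id: Source
    default_temperature_K: 298.15
    temperature_unit: K
    solubility_representation: log10_molar
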