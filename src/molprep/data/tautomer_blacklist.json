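{
  "comment": "Substructures marking improbable tautomers. Aromaticity disruption is enforced separately via the ring-count comparison.",
  "patterns": [
    {
      "name": "terminal_alkene_enol",
      "smarts": "[CX3;H2]=[CX3][OX2H1,OX1-]"
    },
    {
      "name": "geminal_vinyl_diol",
      "smarts": "[OX2H1,OX1-][CX3](=[CX3])[OX2H1,OX1-]"
    },
    {
      "name": "carbanion",
      "smarts": "[#6-]"
    }
  ]
}
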