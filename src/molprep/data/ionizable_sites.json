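{
  "comment": "Curated ionizable-substructure table. Each entry matches a site in either protonation state; 'site' is the index of the titratable atom within the SMARTS match. Mean pKa and spread are literature values for the class. Entries are tried in order; the first entry to claim an atom wins.",
  "sites": [
    {
      "name": "carboxylic_acid",
      "smarts": "[CX3](=[OX1])[OX2H1,OX1-]",
      "site": 2,
      "mean_pka": 3.46,
      "spread": 1.29,
      "deprotonated_charge": -1,
      "protonated_charge": 0
    },
    {
      "name": "sulfonic_acid",
      "smarts": "[SX4](=[OX1])(=[OX1])[OX2H1,OX1-]",
      "site": 3,
      "mean_pka": -1.8,
      "spread": 1.0,
      "deprotonated_charge": -1,
      "protonated_charge": 0
    },
    {
      "name": "phosphate_hydroxyl",
      "smarts": "[PX4](=[OX1])[OX2H1,OX1-]",
      "site": 2,
      "mean_pka": 2.1,
      "spread": 0.9,
      "deprotonated_charge": -1,
      "protonated_charge": 0
    },
    {
      "name": "tetrazole_nh",
      "smarts": "[$([nX3H1]1nnnc1),$([nX3-]1nnnc1)]",
      "site": 0,
      "mean_pka": 4.89,
      "spread": 0.8,
      "deprotonated_charge": -1,
      "protonated_charge": 0
    },
    {
      "name": "guanidine",
      "smarts": "[$([NX2H1;$(N=C(N)N)]),$([NX3H2+;$(N=C(N)N)])]",
      "site": 0,
      "mean_pka": 12.5,
      "spread": 0.5,
      "deprotonated_charge": 0,
      "protonated_charge": 1
    },
    {
      "name": "imidazole_basic_n",
      "smarts": "[$([nX2H0+0]1c[nH]cc1),$([nX3H1+]1c[nH]cc1)]",
      "site": 0,
      "mean_pka": 6.99,
      "spread": 0.5,
      "deprotonated_charge": 0,
      "protonated_charge": 1
    },
    {
      "name": "imide_nh",
      "smarts": "[$([NX3H1;$(N(C=O)C=O)]),$([NX2H0-;$(N(C=O)C=O)])]",
      "site": 0,
      "mean_pka": 9.7,
      "spread": 1.0,
      "deprotonated_charge": -1,
      "protonated_charge": 0
    },
    {
      "name": "sulfonamide_nh",
      "smarts": "[$([NX3H1;$(N[SX4](=O)=O)]),$([NX2H0-;$(N[SX4](=O)=O)])]",
      "site": 0,
      "mean_pka": 10.1,
      "spread": 1.3,
      "deprotonated_charge": -1,
      "protonated_charge": 0
    },
    {
      "name": "aniline",
      "smarts": "[$([NX3H2+0;$(Nc)]),$([NX4H3+;$(Nc)])]",
      "site": 0,
      "mean_pka": 4.6,
      "spread": 0.8,
      "deprotonated_charge": 0,
      "protonated_charge": 1
    },
    {
      "name": "primary_amine",
      "smarts": "[$([NX3H2+0;!$(NC=[O,S,N]);!$(N[SX4]);!$(Nc);!$(N=*)]),$([NX4H3+;!$(NC=[O,S,N]);!$(N[SX4]);!$(Nc)])]",
      "site": 0,
      "mean_pka": 10.6,
      "spread": 0.9,
      "deprotonated_charge": 0,
      "protonated_charge": 1
    },
    {
      "name": "secondary_amine",
      "smarts": "[$([NX3H1+0;!$(NC=[O,S,N]);!$(N[SX4]);!$(Nc);!$(N=*);!$(N[n,o,s]);!$([N]1[CX3]=[CX3,NX2]1)]),$([NX4H2+;!$(NC=[O,S,N]);!$(N[SX4]);!$(Nc)])]",
      "site": 0,
      "mean_pka": 10.9,
      "spread": 1.0,
      "deprotonated_charge": 0,
      "protonated_charge": 1
    },
    {
      "name": "tertiary_amine",
      "smarts": "[$([NX3H0+0;!$(NC=[O,S,N]);!$(N[SX4]);!$(Nc);!$(N=*);!$(N[n,o,s]);!$(N[O,S])]),$([NX4H1+;!$(NC=[O,S,N]);!$(N[SX4]);!$(Nc)])]",
      "site": 0,
      "mean_pka": 10.5,
      "spread": 1.0,
      "deprotonated_charge": 0,
      "protonated_charge": 1
    },
    {
      "name": "aromatic_n_basic",
      "smarts": "[$([nX2H0+0;!$([n]1c[nH]cc1)]),$([nX3H1+;!$([n]1c[nH]cc1)])]",
      "site": 0,
      "mean_pka": 5.2,
      "spread": 1.0,
      "deprotonated_charge": 0,
      "protonated_charge": 1
    },
    {
      "name": "aryl_thiol",
      "smarts": "[$([SX2H1;$(Sc)]),$([SX1-;$(Sc)])]",
      "site": 0,
      "mean_pka": 6.6,
      "spread": 0.6,
      "deprotonated_charge": -1,
      "protonated_charge": 0
    },
    {
      "name": "alkyl_thiol",
      "smarts": "[$([SX2H1;$(S[CX4])]),$([SX1-;$(S[CX4])])]",
      "site": 0,
      "mean_pka": 10.6,
      "spread": 0.8,
      "deprotonated_charge": -1,
      "protonated_charge": 0
    },
    {
      "name": "phenol",
      "smarts": "[$([OX2H1;$(Oc)]),$([OX1-;$(Oc)])]",
      "site": 0,
      "mean_pka": 9.95,
      "spread": 1.2,
      "deprotonated_charge": -1,
      "protonated_charge": 0
    },
    {
      "name": "aliphatic_alcohol",
      "smarts": "[$([OX2H1;$(O[CX4])]),$([OX1-;$(O[CX4])])]",
      "site": 0,
      "mean_pka": 16.0,
      "spread": 1.2,
      "deprotonated_charge": -1,
      "protonated_charge": 0
    }
  ]
}
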