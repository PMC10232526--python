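# Compound library for ThOD stoichiometry (version 1).
# molar_mass in g/mol; formulas restricted to C/H/O/N. Masses are checked at
# load time against standard atomic weights (must agree within 0.5 g/mol).
version: 1
compounds:
  glucose:            {formula: C6H12O6,   molar_mass: 180.16}
  fructose:           {formula: C6H12O6,   molar_mass: 180.16}
  sucrose:            {formula: C12H22O11, molar_mass: 342.30}
  lactose:            {formula: C12H22O11, molar_mass: 342.30}
  anhydroglucose:     {formula: C6H10O5,   molar_mass: 162.14}
  acetic-acid:        {formula: C2H4O2,    molar_mass: 60.05}
  propionic-acid:     {formula: C3H6O2,    molar_mass: 74.08}
  n-butyric-acid:     {formula: C4H8O2,    molar_mass: 88.11}
  iso-butyric-acid:   {formula: C4H8O2,    molar_mass: 88.11}
  lactic-acid:        {formula: C3H6O3,    molar_mass: 90.08}
  ethanol:            {formula: C2H6O,     molar_mass: 46.07}
  glycerol:           {formula: C3H8O3,    molar_mass: 92.09}
  palmitic-acid:      {formula: C16H32O2,  molar_mass: 256.43}
  tripalmitin:        {formula: C51H98O6,  molar_mass: 807.32}
  protein-residue:    {formula: C16H24O5N4, molar_mass: 352.39}
  urea:               {formula: CH4N2O,    molar_mass: 60.06}
  ammonia:            {formula: H3N,       molar_mass: 17.03}
  water:              {formula: H2O,       molar_mass: 18.02}
  methane:            {formula: CH4,       molar_mass: 16.04}
  acetaminophen:      {formula: C8H9NO2,   molar_mass: 151.16}
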