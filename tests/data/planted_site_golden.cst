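CST::BEGIN
  TEMPLATE::   ATOM_MAP: 1 atom_name: C2 C1 C3
  TEMPLATE::   ATOM_MAP: 1 residue3: LIG

  TEMPLATE::   ATOM_MAP: 2 atom_name: CB CA N
  TEMPLATE::   ATOM_MAP: 2 residue3: ALA

  CONSTRAINT:: distanceAB:     3.77   0.10  100.00       0    0
  CONSTRAINT::    angle_A:    74.85  10.00  100.00  360.00    1
  CONSTRAINT::    angle_B:   128.64  10.00  100.00  360.00    1
  CONSTRAINT::  torsion_A:   142.69  10.00  100.00  360.00    1
  CONSTRAINT:: torsion_AB:  -135.72  10.00  100.00  360.00    1
  CONSTRAINT::  torsion_B:   -18.24  10.00  100.00  360.00    1
CST::END

CST::BEGIN
  TEMPLATE::   ATOM_MAP: 1 atom_name: C1 C2 C3
  TEMPLATE::   ATOM_MAP: 1 residue3: LIG

  TEMPLATE::   ATOM_MAP: 2 atom_name: CB CA N
  TEMPLATE::   ATOM_MAP: 2 residue3: ALA

  CONSTRAINT:: distanceAB:     4.26   0.10  100.00       0    0
  CONSTRAINT::    angle_A:    97.61  10.00  100.00  360.00    1
  CONSTRAINT::    angle_B:   119.67  10.00  100.00  360.00    1
  CONSTRAINT::  torsion_A:  -114.64  10.00  100.00  360.00    1
  CONSTRAINT:: torsion_AB:    38.38  10.00  100.00  360.00    1
  CONSTRAINT::  torsion_B:   -21.08  10.00  100.00  360.00    1
CST::END

CST::BEGIN
  TEMPLATE::   ATOM_MAP: 1 atom_name: C3 C1 C2
  TEMPLATE::   ATOM_MAP: 1 residue3: LIG

  TEMPLATE::   ATOM_MAP: 2 atom_name: CB CA N
  TEMPLATE::   ATOM_MAP: 2 residue3: ALA

  CONSTRAINT:: distanceAB:     4.59   0.10  100.00       0    0
  CONSTRAINT::    angle_A:    34.24  10.00  100.00  360.00    1
  CONSTRAINT::    angle_B:   158.11  10.00  100.00  360.00    1
  CONSTRAINT::  torsion_A:  -120.42  10.00  100.00  360.00    1
  CONSTRAINT:: torsion_AB:   135.72  10.00  100.00  360.00    1
  CONSTRAINT::  torsion_B:   -60.95  10.00  100.00  360.00    1
CST::END
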