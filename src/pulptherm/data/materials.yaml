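# Default thermo-physical material library for pulptherm.
#
# Units: youngs_modulus GPa, poissons_ratio dimensionless, density kg/m^3,
# conductivity W/(m K), specific_heat J/(kg K).
#
# The literature table this set descends from prints density values such as
# "2.800" under kg/m^3 and specific heats such as "1.302" under J/(g K);
# read literally those magnitudes are physically absurd (enamel lighter than
# air, composite with the heat capacity of a metal sliver).  The values below
# interpret the period as a thousands separator, which lands every number on
# the standard literature magnitude for that tissue.  The literal reading
# remains selectable via `units_interpretation="literal"` for auditability.
#
# Elastic constants are carried for completeness only; no thermo-mechanical
# coupling is computed.
Enamel:
  youngs_modulus: 80.0
  poissons_ratio: 0.33
  density: 2800.0
  conductivity: 0.84
  specific_heat: 750.0
Dentin:
  youngs_modulus: 20.0
  poissons_ratio: 0.31
  density: 2000.0
  conductivity: 0.36
  specific_heat: 1302.0
Pulp:
  youngs_modulus: 0.003
  poissons_ratio: 0.45
  density: 1000.0
  conductivity: 0.0418
  specific_heat: 4200.0
Filtek Supreme XT:
  youngs_modulus: 5.76
  poissons_ratio: 0.45
  density: 1500.0
  conductivity: 1.18
  specific_heat: 1370.0
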