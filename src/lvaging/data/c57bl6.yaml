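# Reference study conditions: aging wild-type C57BL/6J mice.
# Drivers fitted over ~148 animals; simulation window young (7.5 mon) to
# senescent (30 mon).  Units: mm, mg, months, Pa; pressure driver in mmHg.
drivers:
  total_mass:            # total LV mass, mg
    base: 76.88
    amplitude: 8.92
    onset_months: 8.18
    tau_months: 6.08
  collagen_mass:         # LV collagen mass, mg
    base: 1.21
    amplitude: 1.50
    onset_months: 7.50
    tau_months: 7.23
  pressure:              # end-diastolic transmural pressure, mmHg
    base: 4.5
    amplitude: 3.0
    onset_months: 2.5
    tau_months: 14.0
materials:
  rho_collagen: 1.70     # mg/mm^3
  rho_muscle: 1.06       # mg/mm^3
  E_collagen: 3.2e+7     # Pa
  E_muscle: 5.0e+4       # Pa
  poisson: 0.47
growth:                  # calibrated stretch-induced growth law
  tau_R: 0.22            # months
  D: 2.5
  tau_f: 5.6             # months
simulation:
  t_start: 7.5           # months
  t_end: 30.0            # months
  step_hours: 3.0
  R_i0: 2.0              # mm, free inner radius at t_start
  R_o0: 2.92             # mm, free outer radius at t_start
  hours_per_month: 730.5
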