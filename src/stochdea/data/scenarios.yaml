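# Default scenario catalogue: named input/output variable subsets, each
# giving one "point of view" on relative technical efficiency.
#
# Scenarios S1-S3 and S5 of the original 15-scenario design are not
# enumerated variable-by-variable in any published table, so they are not
# shipped here; user configs may add them.
scenarios:
  - id: S4
    label: Day care health related
    input_vars: [TD1, TD41, ProfTotD1+D41, ProfPsychiD1+D41, ProfPsychoDUED1+D41, PD1+D41]
    output_vars: [UD1, UD41]
  - id: S6
    label: Outpatient care
    input_vars: [TO8+O10, ProfPsychiO8+O10, ProfPsychoO8+O10, ProfDUEO8+O10, ProfTotO8+O10]
    output_vars: [UPrevO8+O10, UIncO8+O10, UFrecO8+O10]
  - id: S7
    label: Placement capacity
    input_vars: [PR2, PR8+R11, PD1+D41, PD4other, PD4other+D2-D3]
    output_vars: [UDischargesR2, UStayR2, UPrevO8+O10, UFrecO8+O10]
  - id: S8
    label: Placement capacity health related
    input_vars: [PR2, PR4-R7, PD1, PD41]
    output_vars: [UDischargesR2, UStayR2, UReAdmissionR2, UPrevO8+O10, UFrecO8+O10]
  - id: S9
    label: Workforce capacity health related
    input_vars: [ProfPsychiR2, ProfPsychoDUER2, ProfPsychiR4-R7, ProfPsychoDUER4-R7, ProfTotD1+D41]
    output_vars: [UDischargesR2, UPrevO8+O10]
  - id: S10
    label: Workforce capacity total
    input_vars: [ProfTotR2, ProfTotR4-R7, ProfTotR8-R13, ProfTotD1+D41, ProfTotD4+D2-D3, ProfTotO8+O10]
    output_vars: [UDischargesR2, UPrevO8+O10]
  - id: S11
    label: Residential and day health related placement with outpatient availability
    input_vars: [PR2, PR4-R7, PD1+D41, TO8+O10]
    output_vars: [UDischargesR2, UStayR2, UReAdmissionR2, UPrevO8+O10, UFrecO8+O10]
  - id: S12
    label: Hospital-community residential and day health related placement with outpatient availability
    input_vars: [PR2, PR8-R13, PD1+D41, TO8+O10]
    output_vars: [UDischargesR2, UStayR2, UPrevO8+O10, UFrecO8+O10]
  - id: S13
    label: Placement capacity of acute residential, day and outpatient care
    input_vars: [PR2, PR8+R11, PR12, PD1+D41, PD4other+D2-D3]
    output_vars: [UDischargesR2, UReAdmissionR2, UPrevO8+O10, UFrecO8+O10]
  - id: S14
    label: Day and residential placement with residential-outpatient workforce
    input_vars: [PR2, PR4-R7, PD1+D41, ProfPsychiR2, ProfTotR4-R7, ProfTotO8+O10]
    output_vars: [UDischargesR2, UPrevO8+O10]
  - id: S15
    label: Health-community residential placement with residential-outpatient workforce
    input_vars: [PR2-R7, ProfTotR2-R7, PR8-R13, ProfTotR8-R13, ProfTotO8+O10]
    output_vars: [UDischargesR2, UReAdmissionR2, UPrevO8+O10]
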