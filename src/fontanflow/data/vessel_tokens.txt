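# Vessel token dictionary for series-description encoding.
# Format: VESSEL: token, token, ...
# Tokens are matched case-insensitively on whole-word boundaries after
# splitting on non-alphanumeric characters; multi-word tokens match as
# phrases.  Edit freely - this file is read at run time.
LPA: lpa, left pulmonary artery, left pulmonary, lt pa, l pa
RPA: rpa, right pulmonary artery, right pulmonary, rt pa, r pa
SVC: svc, superior vena cava, sup vena cava, cava superior
IVC: ivc, inferior vena cava, inf vena cava, cava inferior, fontan conduit
Ao: ao, aorta, aao, aorta ascendens, asc aorta, ascending aorta, dao, aov
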