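# Aglycone skeleton presets for expected-compound library generation.
# Columns: preset, skeleton, neutral_formula, diagnostics ("mz:label;..." anion m/z in Da)
# The "core" preset is the two-skeleton vendor-workflow setting; "extended" covers
# the ten flavonoid aglycones whose conjugates occur in the packaged fixture.
# Diagnostic m/z values are the empirically established negative-mode fragment
# ions of each aglycone (aglycone anion, radical aglycone where typical,
# retro-Diels-Alder A/B-ring fragments, ring-cleavage ions).
preset	skeleton	neutral_formula	diagnostics
core	baicalein	C15H10O5	269.0455:aglycone [M-H]-;241.0504:[M-H-CO]-;251.0348:[M-H-H2O]-;223.0399:[M-H-H2O-CO]-
core	phloretin	C15H14O5	273.0768:aglycone [M-H]-;167.0340:C8H7O4-;137.0233:C7H5O3-;123.0441:C7H7O2-
extended	apigenin	C15H10O5	269.0455:aglycone [M-H]-;268.0373:radical aglycone [Y0-H]-.;117.0344:ring cleavage;149.0239:ring cleavage
extended	baicalein	C15H10O5	269.0455:aglycone [M-H]-;241.0504:[M-H-CO]-;251.0348:[M-H-H2O]-;223.0399:[M-H-H2O-CO]-
extended	eriodictyol	C15H12O6	287.0561:aglycone [M-H]-;151.0027:1,3A- RDA;135.0441:1,3B- RDA;107.0125:ring cleavage
extended	kaempferol	C15H10O6	285.0405:aglycone [M-H]-;151.0027:1,3A- RDA
extended	luteolin	C15H10O6	285.0405:aglycone [M-H]-;151.0027:1,3A- RDA;133.0290:1,3B- RDA;175.0395:ring cleavage
extended	naringenin	C15H12O5	271.0612:aglycone [M-H]-;151.0027:1,3A- RDA;177.0184:ring cleavage;119.0499:1,3B- RDA;107.0126:ring cleavage;93.0333:ring cleavage
extended	phloretin	C15H14O5	273.0768:aglycone [M-H]-;167.0340:C8H7O4-;137.0233:C7H5O3-;123.0441:C7H7O2-
extended	quercetin	C15H10O7	301.0354:aglycone [M-H]-;300.0276:radical aglycone [Y0-H]-.;151.0027:1,3A- RDA;178.9978:ring cleavage;121.0284:ring cleavage;107.0125:ring cleavage
extended	taxifolin	C15H12O7	303.0510:aglycone [M-H]-;285.0410:[M-H-H2O]-;125.0244:C6H5O3-
extended	wogonin	C16H12O5	283.0612:aglycone [M-H]-;268.0373:radical [M-H-CH3]-.;163.0035:ring cleavage
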