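# Default six-gas inert panels for MIGET, ordered by increasing Ostwald
# perfusate-gas partition coefficient (lambda, dimensionless) at ~38 degC.
#
# These are literature-typical values for human blood (hematocrit ~40-45%)
# and for normal saline; they are shipped as documented defaults and every
# value can be overridden per experiment.  The forward and inverse models
# only require a *consistent* panel, not these exact numbers.
schema_version: 1
panels:
  blood:
    SF6: 0.0055   # sulfur hexafluoride, very low solubility
    KR: 0.045     # krypton
    DES: 0.45     # desflurane
    ENF: 1.9      # enflurane
    DEE: 12.0     # diethyl ether
    AC: 300.0     # acetone, very high solubility
  saline:
    SF6: 0.005
    KR: 0.06
    DES: 0.225
    ENF: 0.78
    DEE: 13.0
    AC: 330.0
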