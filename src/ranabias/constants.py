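"""Study-design constants: stage/tissue classes and genetic sexes."""

#: The eight stage/tissue classes samples are drawn from: five Gosner
#: developmental stages (whole bodies) and three adult tissues.
SAMPLE_CLASSES = ("G23", "G27", "G31", "G43", "G46", "brain", "liver", "gonad")

#: Genetic sexes; the sex chromosomes are homomorphic, so sexing is genotypic.
SEXES = ("XX", "XY")

#: Classes pooled over both sexes when building expression profiles (no sex
#: differences are expected before gonadal histological differentiation).
POOLED_CLASSES = ("G23", "G27", "G31", "brain", "liver")

#: The eleven stage/tissue expression classes used for the Tau index, in
#: fixed documented order: five sex-pooled classes followed by six
#: sex-limited ones (XX = female, XY = male; gonad splits into testis/ovary).
PROFILE_CLASSES = (
    "G23",
    "G27",
    "G31",
    "brain",
    "liver",
    "G43_XX",
    "G43_XY",
    "G46_XX",
    "G46_XY",
    "testis",
    "ovary",
)

#: Chromosomes carrying the sex-determining region in this system.
SEX_CHROMOSOMES = (1, 2)
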