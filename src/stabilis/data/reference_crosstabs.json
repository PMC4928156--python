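{
  "description": "Published cross-tabulation counts of OMIM disease-related and polymorphic single residue variations by predicted stability class (|ddG| <= 1 vs > 1 kcal/mol) and solvent accessibility (RSA >= 0.2 vs < 0.2). 'patch' gives the number of variants predicted inside a protein-protein interaction patch. Accessibility in the multimeric set was estimated independently on the isolated chain ('monomer') and on the biological assembly ('complex').",
  "monomeric": {
    "n_proteins": 177,
    "disease": {
      "rsa_source": "monomer",
      "cells": {
        "non_perturbing|accessible": {"count": 562, "patch": 398},
        "non_perturbing|buried": {"count": 756, "patch": 39},
        "perturbing|accessible": {"count": 176, "patch": 120},
        "perturbing|buried": {"count": 907, "patch": 36}
      }
    },
    "polymorphism": {
      "rsa_source": "monomer",
      "cells": {
        "non_perturbing|accessible": {"count": 194, "patch": 110},
        "non_perturbing|buried": {"count": 72, "patch": 3},
        "perturbing|accessible": {"count": 22, "patch": 10},
        "perturbing|buried": {"count": 41, "patch": 0}
      }
    }
  },
  "multimeric": {
    "n_proteins": 191,
    "disease_monomer": {
      "rsa_source": "monomer",
      "cells": {
        "non_perturbing|accessible": {"count": 660, "patch": 465},
        "non_perturbing|buried": {"count": 650, "patch": 24},
        "perturbing|accessible": {"count": 213, "patch": 152},
        "perturbing|buried": {"count": 793, "patch": 24}
      }
    },
    "disease_complex": {
      "rsa_source": "complex",
      "cells": {
        "non_perturbing|accessible": {"count": 550, "patch": 421},
        "non_perturbing|buried": {"count": 760, "patch": 68},
        "perturbing|accessible": {"count": 196, "patch": 140},
        "perturbing|buried": {"count": 810, "patch": 36}
      }
    },
    "polymorphism_monomer": {
      "rsa_source": "monomer",
      "cells": {
        "non_perturbing|accessible": {"count": 198, "patch": 131},
        "non_perturbing|buried": {"count": 84, "patch": 5},
        "perturbing|accessible": {"count": 29, "patch": 21},
        "perturbing|buried": {"count": 45, "patch": 9}
      }
    },
    "polymorphism_complex": {
      "rsa_source": "complex",
      "cells": {
        "non_perturbing|accessible": {"count": 186, "patch": 119},
        "non_perturbing|buried": {"count": 96, "patch": 17},
        "perturbing|accessible": {"count": 29, "patch": 21},
        "perturbing|buried": {"count": 45, "patch": 9}
      }
    }
  }
}
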