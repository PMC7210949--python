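{
  "description": "Power-law coefficients relating the Stokes radius of a protein to its molar mass, log10(Rs/A) = a + b*log10(M/Da), for hydrodynamic conformational classes. Coefficients are the Uversky-type log-log calibrations for natively folded (NF), molten globule (MG), premolten globule (PMG) and unfolded/natively-unfolded chains, determined from size-exclusion chromatography of reference proteins (Uversky, Biochemistry 32:13288, 1993; Uversky, Protein Sci 11:739, 2002; Tcherkasskaya & Uversky, Proteins 44:244, 2001).",
  "default_idp_variant": "coil",
  "sets": {
    "default": {
      "NF":  {"a": -0.254, "b": 0.369},
      "MG":  {"a": -0.053, "b": 0.334},
      "PMG": {"a": -0.239, "b": 0.403},
      "IDP": {"a": -0.551, "b": 0.493}
    },
    "urea_unfolded": {
      "NF":  {"a": -0.254, "b": 0.369},
      "MG":  {"a": -0.053, "b": 0.334},
      "PMG": {"a": -0.239, "b": 0.403},
      "IDP": {"a": -0.649, "b": 0.521}
    },
    "gdmcl_unfolded": {
      "NF":  {"a": -0.254, "b": 0.369},
      "MG":  {"a": -0.053, "b": 0.334},
      "PMG": {"a": -0.239, "b": 0.403},
      "IDP": {"a": -0.723, "b": 0.543}
    }
  },
  "notes": "The 'default' set uses the natively-unfolded coil-like calibration for the IDP class; 'urea_unfolded' and 'gdmcl_unfolded' substitute the chemically denatured calibrations. Band ordering NF < MG < PMG < IDP holds over the 5-100 kDa protein range for every set."
}
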