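"""Published count columns of the seed-storage PFAM summary table.

These are the *inputs* (protein/species counts) from which the percentage
columns are derived; the expected percentages are listed alongside for
checking the arithmetic. Tuples: (pfam_id, description, n_proteins,
n_species, n_qn_rich, n_species_qn_rich, pct_qn_rich, pct_species_qn_rich).
"""

TABLE1_ROWS = [
    ("PF00190", "Cupin", 3973, 70, 302, 54, 7.60, 77.14),
    ("PF01559", "Zein seed storage protein", 161, 3, 119, 3, 73.91, 100.00),
    ("PF13016", "Cys-rich Gliadin N-terminal", 133, 16, 121, 15, 90.98, 93.75),
    ("PF00234", "Protease inhibitor/seed storage/LTP family", 113, 28, 52, 15,
     46.02, 53.57),
    ("PF01535", "PPR repeat", 18, 8, 13, 5, 72.22, 62.50),
    ("PF13041", "PPR repeat family", 17, 8, 13, 5, 76.47, 62.50),
    ("PF04702", "Vicilin N terminal region", 17, 13, 13, 9, 76.47, 69.23),
    ("PF12854", "PPR repeat", 16, 7, 13, 5, 81.25, 71.43),
    ("PF03157", "High molecular weight glutenin subunit", 9, 3, 7, 2,
     77.78, 66.67),
    ("PF13639", "Ring finger domain", 7, 6, 7, 6, 100.00, 100.00),
    ("PF03330", "Lytic transglycolase", 2, 1, 1, 1, 50.00, 100.00),
    ("PF01357", "Pollen allergen", 2, 1, 1, 1, 50.00, 100.00),
    ("PF13446", "A repeated domain in UCH-protein", 1, 1, 1, 1, 100.00, 100.00),
    ("PF03145", "Seven in absentia protein family", 1, 1, 1, 1, 100.00, 100.00),
    ("Total", "", 4487, 70, 601, 59, 13.39, 84.29),
]
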