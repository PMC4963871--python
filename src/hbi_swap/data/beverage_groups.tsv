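kind	pattern	group
# --- labels: longest normalized-prefix match wins ---
label	water	WATER
label	tap water	WATER
label	bottled water	WATER
label	coffee, unsweetened	COFFEE_TEA_UNSWEETENED
label	coffee, black	COFFEE_TEA_UNSWEETENED
label	tea, unsweetened	COFFEE_TEA_UNSWEETENED
label	coffee, with non-caloric sweetener	DIET
label	tea, with non-caloric sweetener	DIET
label	coffee, sweetened	SSB
label	tea, sweetened	SSB
label	soda	SSB
label	soda, diet	DIET
label	diet soda	DIET
label	diet beverage	DIET
label	fruit drink	SSB
label	energy drink	SSB
label	sports drink	SSB
label	meal replacement	SSB
label	milk, skim	LOW_FAT_MILK
label	milk, 1%	LOW_FAT_MILK
label	milk, soy	LOW_FAT_MILK
label	milk, 2%	WHOLE_MILK
label	milk, whole	WHOLE_MILK
label	juice	JUICE_100
label	orange juice	JUICE_100
label	apple juice	JUICE_100
label	100% juice	JUICE_100
label	beer	ALCOHOL
label	wine	ALCOHOL
label	liquor	ALCOHOL
# --- food codes: exact or prefix match ---
code	94000100	WATER
code	92302000	COFFEE_TEA_UNSWEETENED
code	11112110	LOW_FAT_MILK
code	92410510	DIET
code	61210000	JUICE_100
code	93101000	ALCOHOL
code	11111000	WHOLE_MILK
code	92410310	SSB
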