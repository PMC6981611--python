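rule_id	class	conditions	cover	misclassified	accuracy_pct
1	QSP	GRAR740101 <= 0.9055 & MANP780101 > 0.7495 & PRAM900102 > 0.848 & QIAN880137 <= 0.237	10	0	100.00
2	QSP	PONP800102 > -0.751 & PONP800102 <= 1.0025 & QIAN880137 <= -0.104 & ROBB760104 <= 0.3645 & ROBB760104 > -0.5205	61	1	98.36
3	QSP	PALJ810111 <= 1.369 & QIAN880137 > -0.104 & QIAN880137 <= 0.417 & ROBB760113 <= 0.5975 & AURR980102 <= 0.6955	21	2	90.48
4	QSP	GEIM800101 > -0.3135 & GRAR740101 > -0.176 & ISOY800107 <= 1.367 & MANP780101 > -0.3325 & PALJ810111 <= 1.0905 & QIAN880137 <= -0.0985	94	6	93.62
5	QSP	PALJ810111 > -0.786 & QIAN880137 > 0.237 & QIAN880137 > 0.403 & ROBB760113 > 0.5975 & AURR980102 <= 0.811 & KUMS000103 <= 0.793	45	7	84.44
6	QSP	GRAR740101 <= 0.341 & ISOY800107 <= -0.089 & PALJ810111 <= 1.2455 & QIAN880137 > -0.009 & ROBB760113 <= -0.0285	17	3	82.35
7	QSP	GRAR740101 > -0.708 & PRAM900102 <= 1.2985 & QIAN880137 > -0.104 & QIAN880137 <= 1.105 & AURR980102 <= 0.6585 & KUMS000103 <= 0.974	94	28	70.21
8	QSP	PONP800102 <= 1.1095 & PRAM900102 <= 0.8295 & QIAN880137 <= 0.2625 & QIAN880137 > -0.9055 & ROBB760113 > -0.5875 & ROBB760113 <= 1.031	121	15	87.60
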