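# Head musculoskeletal registry: 181 anatomical units, transcribed verbatim from
# the published numbered label list (printed typos kept: "Platsma", "Lateral rectus
# lefts", "Sternothryroideus"). tissue_class is recorded here, not derived at load
# time: ids 1-29 and 34-45 bone, 30-33 cartilage, 46-181 muscle. side is recorded
# from the left/right suffix of each printed name, otherwise median.
# NOTE: the printed list gives the range "39-45 Cervical vertebrae 1 to 6" -- seven
# ids for six names; seven vertebra nodes are kept, numbered 1-7.
node_id,name,tissue_class,side
1,Occipital,bone,median
2,Parietal left,bone,left
3,Parietal right,bone,right
4,Temporal left,bone,left
5,Temporal right,bone,right
6,Sphenoid,bone,median
7,Zygomatic left,bone,left
8,Zygomatic right,bone,right
9,Frontal,bone,median
10,Ethmoidal,bone,median
11,Nasal left,bone,left
12,Nasal right,bone,right
13,Maxilla left,bone,left
14,Maxilla right,bone,right
15,Lacrimal left,bone,left
16,Lacrimal right,bone,right
17,Palatine left,bone,left
18,Palatine right,bone,right
19,Nasal concha left,bone,left
20,Nasal concha right,bone,right
21,Vomer,bone,median
22,Malleus left,bone,left
23,Malleus right,bone,right
24,Incus left,bone,left
25,Incus right,bone,right
26,Stapes left,bone,left
27,Stapes right,bone,right
28,Mandible,bone,median
29,Hyoid bone,bone,median
30,Thyroid cartilage,cartilage,median
31,Arytenoid cartilage left,cartilage,left
32,Arytenoid cartilage right,cartilage,right
33,Cricoid cartilage,cartilage,median
34,Sternum,bone,median
35,Clavicle left,bone,left
36,Clavicle right,bone,right
37,Scapula left,bone,left
38,Scapula right,bone,right
39,Cervical vertebra 1,bone,median
40,Cervical vertebra 2,bone,median
41,Cervical vertebra 3,bone,median
42,Cervical vertebra 4,bone,median
43,Cervical vertebra 5,bone,median
44,Cervical vertebra 6,bone,median
45,Cervical vertebra 7,bone,median
46,Tensor tympani left,muscle,left
47,Tensor tympani right,muscle,right
48,Stapedius left,muscle,left
49,Stapedius right,muscle,right
50,Levator palpebrae superioris left,muscle,left
51,Levator palpebrae superioris right,muscle,right
52,Superior oblique left,muscle,left
53,Superior oblique right,muscle,right
54,Inferior oblique left,muscle,left
55,Inferior oblique right,muscle,right
56,Superior rectus left,muscle,left
57,Superior rectus right,muscle,right
58,Inferior rectus left,muscle,left
59,Inferior rectus right,muscle,right
60,Medial rectus left,muscle,left
61,Medial rectus right,muscle,right
62,Lateral rectus lefts,muscle,left
63,Lateral rectus right,muscle,right
64,Platsma left,muscle,left
65,Platsma right,muscle,right
66,Occipitalis left,muscle,left
67,Occipitalis right,muscle,right
68,Auricularis posterior left,muscle,left
69,Auricularis posterior right,muscle,right
70,Risorius left,muscle,left
71,Risorius right,muscle,right
72,Zygomaticus major left,muscle,left
73,Zygomaticus major right,muscle,right
74,Zygomaticus minor left,muscle,left
75,Zygomaticus minor right,muscle,right
76,Frontalis left,muscle,left
77,Frontalis right,muscle,right
78,Temporoparietalis left,muscle,left
79,Temporoparietalis right,muscle,right
80,Auricularis anterior left,muscle,left
81,Auricularis anterior right,muscle,right
82,Auricularis superior left,muscle,left
83,Auricularis superior right,muscle,right
84,Orbicularis oculi left,muscle,left
85,Orbicularis oculi right,muscle,right
86,Depressor supercilii left,muscle,left
87,Depressor supercilii right,muscle,right
88,Corrugator supercilii left,muscle,left
89,Corrugator supercilii right,muscle,right
90,Levator labii superioris alaeque nasi left,muscle,left
91,Levator labii superioris alaeque nasi right,muscle,right
92,Procerus left,muscle,left
93,Procerus right,muscle,right
94,Buccinatorius left,muscle,left
95,Buccinatorius right,muscle,right
96,Levator labii superioris left,muscle,left
97,Levator labii superioris right,muscle,right
98,Nasalis left,muscle,left
99,Nasalis right,muscle,right
100,Depressor septi nasi left,muscle,left
101,Depressor septi nasi right,muscle,right
102,Levator anguli oris facialis left,muscle,left
103,Levator anguli oris facialis right,muscle,right
104,Orbicularis oris left,muscle,left
105,Orbicularis oris right,muscle,right
106,Depressor labii inferioris left,muscle,left
107,Depressor labii inferioris right,muscle,right
108,Depressor anguli oris left,muscle,left
109,Depressor anguli oris right,muscle,right
110,Mentalis left,muscle,left
111,Mentalis right,muscle,right
112,Mylohyoideus left,muscle,left
113,Mylohyoideus right,muscle,right
114,Digastricus anterior left,muscle,left
115,Digastricus anterior right,muscle,right
116,Tensor veli palatini left,muscle,left
117,Tensor veli palatini right,muscle,right
118,Masseter left,muscle,left
119,Masseter right,muscle,right
120,Temporalis (main body) left,muscle,left
121,Temporalis (main body) right,muscle,right
122,Pterygoideus lateralis (pars. sup.) left,muscle,left
123,Pterygoideus lateralis (pars. sup.) right,muscle,right
124,Pterygoideus lateralis (pars. inf.) left,muscle,left
125,Pterygoideus lateralis (pars. inf.) right,muscle,right
126,Pterygoideus medialis left,muscle,left
127,Pterygoideus medialis right,muscle,right
128,Stylohyoideus left,muscle,left
129,Stylohyoideus right,muscle,right
130,Digastricus posterior left,muscle,left
131,Digastricus posterior right,muscle,right
132,Stylopharyngeus left,muscle,left
133,Stylopharyngeus right,muscle,right
134,Trapezius left,muscle,left
135,Trapezius right,muscle,right
136,Sternocleidomastoideus left,muscle,left
137,Sternocleidomastoideus right,muscle,right
138,Constrictor pharyngis medius left,muscle,left
139,Constrictor pharyngis medius right,muscle,right
140,Constrictor pharyngis inferior left,muscle,left
141,Constrictor pharyngis inferior right,muscle,right
142,Cricothyroideus left,muscle,left
143,Cricothyroideus right,muscle,right
144,Constrictor pharyngis superior left,muscle,left
145,Constrictor pharyngis superior right,muscle,right
146,Palatopharyngeus left,muscle,left
147,Palatopharyngeus right,muscle,right
148,Levator veli palatini left,muscle,left
149,Levator veli palatini right,muscle,right
150,Salpingopharyngeus left,muscle,left
151,Salpingopharyngeus right,muscle,right
152,Thyroarytenoideus left,muscle,left
153,Thyroarytenoideus right,muscle,right
154,Cricoarytenoideus lateralis left,muscle,left
155,Cricoarytenoideus lateralis right,muscle,right
156,Arytenoideus transversus left,muscle,left
157,Arytenoideus transversus right,muscle,right
158,Arytenoideus obliquus left,muscle,left
159,Arytenoideus obliquus right,muscle,right
160,Cricoarytenoideus posterior left,muscle,left
161,Cricoarytenoideus posterior right,muscle,right
162,Geniohyoideus left,muscle,left
163,Geniohyoideus right,muscle,right
164,Genioglossus left,muscle,left
165,Genioglossus right,muscle,right
166,Hyoglossus left,muscle,left
167,Hyoglossus right,muscle,right
168,Styloglossus left,muscle,left
169,Styloglossus right,muscle,right
170,Palatoglossus left,muscle,left
171,Palatoglossus right,muscle,right
172,Sternohyoideus left,muscle,left
173,Sternohyoideus right,muscle,right
174,Omohyoideus (pars. sup.) left,muscle,left
175,Omohyoideus (pars. sup.) right,muscle,right
176,Omohyoideus (pars. inf.) left,muscle,left
177,Omohyoideus (pars. inf.) right,muscle,right
178,Sternothryroideus left,muscle,left
179,Sternothryroideus right,muscle,right
180,Thyrohyoideus left,muscle,left
181,Thyrohyoideus right,muscle,right
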