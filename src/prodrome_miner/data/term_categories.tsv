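# surface	category	english_gloss
# Japanese surfaces (as emitted by the built-in lexicon tokenizer)
息切れ	respiratory	Breathlessness
呼吸困難	respiratory	Dyspnea
呼吸苦	respiratory	Breathing discomfort
酸素	respiratory	Oxygen
疼痛	pain_analgesic	Pain
痛み	pain_analgesic	Soreness
頭痛	pain_analgesic	Headache
リリカ	pain_analgesic	Lyrica (pregabalin)
オキシコドン	pain_analgesic	Oxycodone
オキノーム	pain_analgesic	Oxinorm (oxycodone)
オピオイド	pain_analgesic	Opioid
ロキソニン	pain_analgesic	Loxonin (loxoprofen)
食欲不振	appetite	Inappetence
食事摂取	appetite	Food intake
嘔気	appetite	Feeling queasy
嘔吐	appetite	Vomiting
ノバミン	appetite	Novamin (prochlorperazine)
せん妄	delirium	Delirium
貧血	anemia	Anemia
出血	bleeding	Bleeding
傾眠	sleepiness	Sleepiness
皮疹	skin_eruption	Skin eruption
# English glosses of the reported category membership
Breathlessness	respiratory	Breathlessness
Shortness of breath	respiratory	Shortness of breath
O2	respiratory	Oxygen
Soreness	pain_analgesic	Soreness
Ache	pain_analgesic	Ache
Pain	pain_analgesic	Pain
Pain-precordial	pain_analgesic	Precordial pain
NRS	pain_analgesic	Numeric rating scale
Lyrica	pain_analgesic	Lyrica (pregabalin)
Opioid	pain_analgesic	Opioid
Oxinorm	pain_analgesic	Oxinorm (oxycodone)
OxyContin	pain_analgesic	OxyContin (oxycodone)
OxyContin-increased	pain_analgesic	OxyContin increased
Oxycodone	pain_analgesic	Oxycodone
Inappetence	appetite	Inappetence
Food-intake	appetite	Food intake
Feeling-queasy	appetite	Feeling queasy
Novamin	appetite	Novamin (prochlorperazine)
Delirium	delirium	Delirium
Anemia	anemia	Anemia
Bleeding	bleeding	Bleeding
Sleepiness	sleepiness	Sleepiness
Skin eruption	skin_eruption	Skin eruption
AM	other	AM
Hgb	other	Hemoglobin
nasal	other	Nasal
Sp	other	Sp
Drain	other	Drain
Pattern	other	Pattern
Face-scale	other	Face scale
Rescue	other	Rescue
Worsening	other	Worsening
Most	other	Most
Right-chest	other	Right chest
Right-back	other	Right back
Impact	other	Impact
Possibility	other	Possibility
Family	other	Family
Conversation	other	Conversation
Improvement	other	Improvement
Start	other	Start
Going-out	other	Going out
Intermittent	other	Intermittent
Face	other	Face
Course	other	Course
Watchful-waiting	other	Watchful waiting
Relief	other	Relief
Consideration	other	Consideration
Cause	other	Cause
Reduction	other	Reduction
After	other	After
Today	other	Today
Restart	other	Restart
Yesterday	other	Yesterday
Last night	other	Last night
Residual	other	Residual
Use	other	Use
Usage	other	Usage
Test/Trial	other	Test/Trial
Timing	other	Timing
Awareness	other	Awareness
Bleeding source	other	Bleeding source
Meal	other	Meal
Worry	other	Worry
Doctor	other	Doctor
Before	other	Before
Exacerbation	other	Exacerbation
Increase	other	Increase
During movement	other	During movement
Response	other	Response
Okay	other	Okay
Discontinuation	other	Discontinuation
Morning	other	Morning
Condition	other	Condition
Decrease	other	Decrease
Degree	other	Degree
Fall	other	Fall
Fall-risk	other	Fall risk
Administration	other	Administration
Oral administration	other	Oral administration
Medical condition	other	Medical condition
Anxiety	other	Anxiety
Average	other	Average
This day	other	This day
Tomorrow	other	Tomorrow
Night	other	Night
Drug name	other	Drug name
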