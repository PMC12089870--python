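surface,category,is_abbreviation
wife,spouse,false
husband,spouse,false
spouse,spouse,false
partner,spouse,false
widow,spouse,false
widower,spouse,false
hubby,spouse,true
son,child,false
daughter,child,false
dtr,child,true
stepson,child,false
stepdaughter,child,false
son in law,child,false
daughter in law,child,false
in law,child,false
mother,parent,false
father,parent,false
mom,parent,false
dad,parent,false
parent,parent,false
stepmother,parent,false
stepfather,parent,false
sister,other,false
brother,other,false
sibling,other,false
grandson,other,false
granddaughter,other,false
grandchild,other,false
grandmother,other,false
grandfather,other,false
niece,other,false
nephew,other,false
aunt,other,false
uncle,other,false
cousin,other,false
friend,other,false
neighbor,other,false
caregiver,other,false
caretaker,other,false
carer,other,false
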