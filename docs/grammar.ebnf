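(* Concrete grammar of the causal behaviour language (CBL), UTF-8, *.cbl.
   The dialect is line-oriented: every declaration, causal relation and
   observation spot sits on its own line; blocks open at end of line and
   close with a lone "}".  "#" starts a comment running to end of line. *)

program     = { line } ;
line        = blank | declaration | relation | observation
            | context-open | compartment-open | block-close ;

blank       = [ comment ] newline ;
comment     = "#" , { any-char - newline } ;

(* agents: a constant names a concrete part and starts upper-case; a
   variable abstracts a class of parts and starts lower-case *)
ident       = letter , { letter | digit | "_" } ;
constant    = upper-letter , { letter | digit | "_" } ;
variable    = lower-letter , { letter | digit | "_" } ;
label       = ident ;
number      = [ "+" | "-" ] , ( digits , [ "." , { digit } ] | "." , digits )
            , [ ( "e" | "E" ) , [ "+" | "-" ] , digits ] ;

(* attribute declarations: one capacity chain (least capacity first) and
   any number of incomparable pairs *)
declaration = ident , ":" , "{" , attr-group , { "," , attr-group } , "}" ;
attr-group  = chain | unequal ;
chain       = label , "<" , label , { "<" , label } ;
unequal     = label , "/~" , label ;

(* state literals: presence by name, absence by "!", optional symbolic or
   numeric activity qualifier *)
literal     = [ "!" ] , ident , [ qualifier ] ;
qualifier   = "(" , ( label | number ) , ")"
            | "[" , number , "," , number , "]" ;
literal-set = literal , { "&" , literal } ;

(* causal relations; the arrow must be surrounded by whitespace.
   "->" normal, "o->" persistent, "+->" remnant are the primitives;
   "-+" strong activation and "--" strong inhibition are macros that
   expand to pairs of primitives *)
relation    = literal-set , arrow , literal-set ;
arrow       = "->" | "o->" | "+->" | "-+" | "--" ;

observation = "obs_" , ident , "::" , literal ;   (* top level only *)

(* scoping blocks; contexts gate the enclosed relations on an agent,
   compartments make them local *)
context-open     = "[" , ident , "]" , "{" ;
compartment-open = ident , "{" ;
block-close      = "}" ;
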